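"""Protein graphs from secondary-structure assignments and coordinates.

A protein graph (P-graph) here has one vertex per secondary-structure
segment and an edge between two segments whenever their representative
points lie within the AVG threshold — the mean pairwise distance over
all vertex pairs — of each other.  The construction is:

1. reduce each residue's DSSP code to three classes:
   G/H/I -> H (helix), T/E/B -> T (turn/strand), C -> C (coil); the
   codes the three-class table omits (blank, S bend) also fall to coil,
   the catch-all class of standard 3-state reductions;
2. merge maximal runs of the same class into segments;
3. represent each segment by the centroid of its residues' Cα
   coordinates (in Å);
4. join segments at centroid distance <= AVG (inclusive).

A disconnected result is legal — sparse structures can fall apart at
low density — and is reported rather than rejected.

Inputs are either real DSSP output files (fixed-column dialect) or a
plain residue table (TSV with chain, residue number, DSSP code, x, y,
z), which keeps the pipeline testable without any external tool.  Cα
coordinates can also be pulled from a PDB file when the per-residue
codes come from elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import Graph, pairwise_distances

__all__ = [
    "SSERecord",
    "PGraph",
    "ResidueTable",
    "classify_sse",
    "segment",
    "representative",
    "avg_threshold",
    "build",
    "segments_from_residues",
    "read_residue_tsv",
    "read_dssp",
    "read_pdb_ca",
]

#: DSSP single-letter codes reduced to the three-class alphabet
_THREE_CLASS = {
    "G": "H", "H": "H", "I": "H",
    "T": "T", "E": "T", "B": "T",
    "C": "C",
}
#: codes normalized to coil before classification
_COIL_ALIASES = {" ", "", "-", "S"}


def classify_sse(code: str) -> str:
    """Reduce one DSSP code to H (helix), T (turn/strand) or C (coil)."""
    normalized = "C" if code in _COIL_ALIASES else code.upper()
    try:
        return _THREE_CLASS[normalized]
    except KeyError:
        raise ValueError(
            f"unknown secondary-structure code {code!r} "
            f"(expected one of {sorted(_THREE_CLASS)}, blank, or S)"
        ) from None


@dataclass(frozen=True)
class SSERecord:
    """One secondary-structure segment with its representative point (Å)."""

    chain: str
    start_residue: int
    end_residue: int
    sse_class: str
    representative: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ValueError("segment start must not exceed its end")
        if self.sse_class not in ("H", "T", "C"):
            raise ValueError(f"sse_class must be H, T or C, got {self.sse_class!r}")


@dataclass(frozen=True)
class PGraph:
    """A built protein graph: topology + geometry, the segments behind its
    vertices (vertex i is ``segments[i-1]``), and the AVG threshold used."""

    graph: Graph
    segments: tuple[SSERecord, ...]
    threshold: float


def segment(classes: Sequence[str]) -> list[tuple[int, int, str]]:
    """Run-length segmentation: maximal runs of one class, 1-based inclusive."""
    if not classes:
        raise ValueError("empty class sequence")
    out: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            out.append((start + 1, i, classes[start]))
            start = i
    return out


def representative(
    rng: tuple[int, int], coords: Sequence[Sequence[float] | None]
) -> tuple[float, float, float]:
    """Centroid of the Cα coordinates over a 1-based inclusive residue range."""
    start, end = rng
    block = []
    for residue in range(start, end + 1):
        xyz = coords[residue - 1]
        if xyz is None or np.isnan(xyz).any():
            raise ValueError(f"missing Cα coordinate for residue {residue}")
        block.append(xyz)
    return tuple(np.asarray(block, dtype=float).mean(axis=0))


def avg_threshold(representatives: Sequence[Sequence[float]]) -> float:
    """AVG: mean Euclidean distance over all unordered vertex pairs."""
    pts = np.asarray(representatives, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("AVG threshold needs at least two points")
    geo = pairwise_distances(pts)
    return float(geo[np.triu_indices(pts.shape[0], k=1)].mean())


def build(segments: Sequence[SSERecord]) -> PGraph:
    """Assemble the P-graph: edge iff centroid distance <= AVG (inclusive)."""
    if len(segments) < 2:
        raise ValueError("need at least two segments to build a graph")
    pts = np.array([s.representative for s in segments], dtype=float)
    threshold = avg_threshold(pts)
    geo = pairwise_distances(pts)
    n = len(segments)
    edges = [
        (i + 1, j + 1) for i, j in combinations(range(n), 2) if geo[i, j] <= threshold
    ]
    graph = Graph(n=n, edges=frozenset(edges), geometry=geo)
    return PGraph(graph=graph, segments=tuple(segments), threshold=threshold)


# -- residue-level input ---------------------------------------------------

#: per-residue input: chain id, residue number, raw DSSP code, Cα x/y/z (Å)
ResidueTable = pd.DataFrame

_RESIDUE_COLUMNS = ["chain", "resnum", "sse_code", "x", "y", "z"]


def segments_from_residues(table: ResidueTable, per_chain: bool = False):
    """Turn a residue table into SSERecords (one joint graph by default).

    Multimeric structures are treated as one joint vertex set over all
    chains unless ``per_chain`` is set, in which case a dict mapping
    chain id to its own segment list is returned.
    """
    missing = [c for c in _RESIDUE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"residue table lacks columns {missing}")
    if per_chain:
        return {
            str(chain): _chain_segments(group)
            for chain, group in table.groupby("chain", sort=True)
        }
    joint: list[SSERecord] = []
    for _, group in table.groupby("chain", sort=True):
        joint.extend(_chain_segments(group))
    return joint


def _chain_segments(group: pd.DataFrame) -> list[SSERecord]:
    group = group.sort_values("resnum")
    classes = [classify_sse(c) for c in group["sse_code"]]
    coords = group[["x", "y", "z"]].to_numpy(dtype=float)
    resnums = group["resnum"].to_numpy(dtype=int)
    chain = str(group["chain"].iloc[0])
    records = []
    for start, end, cls in segment(classes):
        rep = representative((start, end), coords)
        records.append(
            SSERecord(
                chain=chain,
                start_residue=int(resnums[start - 1]),
                end_residue=int(resnums[end - 1]),
                sse_class=cls,
                representative=rep,
            )
        )
    return records


def read_residue_tsv(path: str | Path) -> ResidueTable:
    """Read the plain residue-table format (chain, resnum, sse_code, x, y, z)."""
    table = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=_RESIDUE_COLUMNS,
        dtype={"chain": str, "sse_code": str},
    )
    table["resnum"] = table["resnum"].astype(int)
    return table


# DSSP fixed columns (0-based slices of each residue line)
_DSSP_RESNUM = slice(5, 10)
_DSSP_CHAIN = slice(11, 12)
_DSSP_SS = slice(16, 17)
_DSSP_XCA = slice(115, 122)
_DSSP_YCA = slice(122, 129)
_DSSP_ZCA = slice(129, 136)


def read_dssp(path: str | Path) -> ResidueTable:
    """Parse a DSSP output file into the residue table.

    Only the columns this pipeline needs are read: residue number, chain,
    summary secondary-structure code, and the Cα coordinates.  Chain-break
    records ('!' residues) are skipped.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.lstrip().startswith("#  RESIDUE")) + 1
    except StopIteration:
        raise ValueError(f"{path} does not look like a DSSP file (no '#  RESIDUE' header)")
    rows = []
    for line in lines[start:]:
        if len(line) < 136 or line[13] == "!":
            continue
        rows.append(
            {
                "chain": line[_DSSP_CHAIN].strip() or "A",
                "resnum": int(line[_DSSP_RESNUM]),
                "sse_code": line[_DSSP_SS],
                "x": float(line[_DSSP_XCA]),
                "y": float(line[_DSSP_YCA]),
                "z": float(line[_DSSP_ZCA]),
            }
        )
    if not rows:
        raise ValueError(f"no residue records found in {path}")
    return pd.DataFrame(rows, columns=_RESIDUE_COLUMNS)


def read_pdb_ca(path: str | Path) -> dict[tuple[str, int], tuple[float, float, float]]:
    """Extract Cα coordinates from a PDB file, keyed by (chain, resnum)."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("pgraph", str(path))
    model = next(structure.get_models())
    out: dict[tuple[str, int], tuple[float, float, float]] = {}
    for chain in model:
        for residue in chain:
            if "CA" in residue:
                out[(chain.id, residue.id[1])] = tuple(residue["CA"].coord.astype(float))
    return out
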