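"""Tabular report writers for sweeps and pairwise spectral comparisons.

Numeric cells print at three decimals; the NaC (disconnected) and NaN
(no candidate edge) sentinels are literal cell strings, and the density
under a NaC cell prints as "-", mirroring the published table layout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .adjustment import SweepRow

__all__ = ["verdict", "sweep_frame", "sweep_tsv", "pairwise_frame", "pairwise_tsv"]

PRECISION = 3


def verdict(old: float, new: float, precision: int = 2, rel_tol: float = 0.005) -> str:
    """Compare old/new spectral distances: '+' better, '=' not bad, '-' worse.

    Distances equal after rounding to ``precision`` decimals, or within
    ``rel_tol`` relatively, count as '='; otherwise a smaller new
    distance earns '+'.
    """
    ro, rn = round(old, precision), round(new, precision)
    if ro == rn:
        return "="
    scale = max(abs(old), abs(new))
    if scale > 0 and abs(old - new) / scale <= rel_tol:
        return "="
    return "+" if new < old else "-"


def _offset_label(offset: int) -> str:
    if offset == 0:
        return "AVG"
    return f"{'+' if offset > 0 else '-'}{abs(offset)}e"


def _entropy_cell(row: SweepRow) -> str:
    if row.status != "ok":
        return row.status
    return f"{row.entropy:.{PRECISION}f}"


def _density_cell(row: SweepRow) -> str:
    if row.status == "NaC" or row.density is None:
        return "-"
    return f"{row.density:.{PRECISION}f}"


def sweep_frame(rows_by_label: dict[str, list[SweepRow]]) -> pd.DataFrame:
    """Sweep table: per graph an entropy row and a density ('Dens') row."""
    records = {}
    for label, rows in rows_by_label.items():
        ordered = sorted(rows, key=lambda r: r.offset)
        columns = [_offset_label(r.offset) for r in ordered]
        records[label] = pd.Series([_entropy_cell(r) for r in ordered], index=columns)
        records[f"{label} Dens"] = pd.Series(
            [_density_cell(r) for r in ordered], index=columns
        )
    return pd.DataFrame(records).T


def sweep_tsv(rows_by_label: dict[str, list[SweepRow]]) -> str:
    frame = sweep_frame(rows_by_label)
    return frame.to_csv(sep="\t", index_label="PID")


def pairwise_frame(
    labels: Sequence[str],
    old: np.ndarray,
    new: np.ndarray,
    precision: int = 2,
) -> pd.DataFrame:
    """Upper-triangular old/new/verdict comparison of two distance matrices.

    One row triple (Old, New, Result) per graph; cells below the diagonal
    are '·' as in the published layout.
    """
    old = np.asarray(old, dtype=float)
    new = np.asarray(new, dtype=float)
    k = len(labels)
    if old.shape != (k, k) or new.shape != (k, k):
        raise ValueError("matrices must be square and match the label count")
    rows = {}
    for i, label in enumerate(labels):
        old_row, new_row, res_row = [], [], []
        for j in range(k):
            if j <= i:
                old_row.append("·")
                new_row.append("·")
                res_row.append("·")
            else:
                old_row.append(f"{old[i, j]:.{precision}f}")
                new_row.append(f"{new[i, j]:.{precision}f}")
                res_row.append(verdict(old[i, j], new[i, j], precision=precision))
        rows[(label, "Old")] = old_row
        rows[(label, "New")] = new_row
        rows[(label, "Result")] = res_row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["PID", "field"])
    return frame


def pairwise_tsv(
    labels: Sequence[str], old: np.ndarray, new: np.ndarray, precision: int = 2
) -> str:
    return pairwise_frame(labels, old, new, precision=precision).to_csv(sep="\t")


def distance_matrix_tsv(labels: Sequence[str], matrix: np.ndarray) -> str:
    """Plain labeled distance matrix as TSV (3-decimal cells)."""
    frame = pd.DataFrame(np.round(matrix, PRECISION), index=labels, columns=labels)
    return frame.to_csv(sep="\t", index_label="")
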