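"""Protein-graph construction from secondary structure and coordinates."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pgentropy import io
from pgentropy.graph import Graph, density
from pgentropy.pgraph import (
    SSERecord,
    avg_threshold,
    build,
    classify_sse,
    read_dssp,
    read_pdb_ca,
    read_residue_tsv,
    representative,
    segment,
    segments_from_residues,
)

UNIT_SQUARE_3D = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (1.0, 1.0, 0.0), (0.0, 1.0, 0.0)]


def square_segments() -> list[SSERecord]:
    classes = ["H", "T", "C", "H"]
    return [
        SSERecord("A", i + 1, i + 1, classes[i], UNIT_SQUARE_3D[i])
        for i in range(4)
    ]


class TestClassify:
    @pytest.mark.parametrize(
        "code, cls",
        [("G", "H"), ("H", "H"), ("I", "H"), ("T", "T"), ("E", "T"), ("B", "T"),
         ("C", "C"), (" ", "C"), ("", "C"), ("S", "C"), ("-", "C")],
    )
    def test_three_class_reduction(self, code, cls):
        assert classify_sse(code) == cls

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown secondary-structure code"):
            classify_sse("Z")


class TestSegmentation:
    @pytest.mark.parametrize(
        "classes, expected",
        [
            ("HHHTTC", [(1, 3, "H"), (4, 5, "T"), (6, 6, "C")]),
            ("H", [(1, 1, "H")]),
            ("HTHTH", [(1, 1, "H"), (2, 2, "T"), (3, 3, "H"), (4, 4, "T"), (5, 5, "H")]),
        ],
    )
    def test_run_length_segments(self, classes, expected):
        assert segment(list(classes)) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            segment([])


class TestRepresentative:
    def test_single_residue(self):
        coords = [(1.0, 2.0, 3.0)]
        assert representative((1, 1), coords) == (1.0, 2.0, 3.0)

    def test_two_residue_midpoint(self):
        coords = [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0)]
        assert representative((1, 2), coords) == (1.0, 0.0, 0.0)

    def test_three_collinear(self):
        coords = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (2.0, 0.0, 0.0)]
        assert representative((1, 3), coords) == (1.0, 0.0, 0.0)

    def test_missing_coordinate_names_residue(self):
        coords = [(0.0, 0.0, 0.0), None, (2.0, 0.0, 0.0)]
        with pytest.raises(ValueError, match="residue 2"):
            representative((1, 3), coords)


class TestAvgThreshold:
    def test_two_points(self):
        assert avg_threshold([(0, 0, 0), (4, 0, 0)]) == pytest.approx(4.0)

    def test_unit_square(self):
        expected = (4 * 1 + 2 * math.sqrt(2)) / 6
        assert avg_threshold(UNIT_SQUARE_3D) == pytest.approx(expected)

    def test_collinear_triple(self):
        assert avg_threshold([(0, 0, 0), (1, 0, 0), (2, 0, 0)]) == pytest.approx(4 / 3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            avg_threshold([(0, 0, 0)])


class TestBuild:
    def test_unit_square_becomes_c4(self):
        # sides (1) <= AVG (~1.138) < diagonals (sqrt 2): the cycle appears
        pg = build(square_segments())
        assert pg.graph.edges == frozenset([(1, 2), (2, 3), (3, 4), (1, 4)])
        assert pg.threshold == pytest.approx((4 + 2 * math.sqrt(2)) / 6)

    def test_two_segments_always_joined(self):
        segs = [
            SSERecord("A", 1, 3, "H", (0.0, 0.0, 0.0)),
            SSERecord("A", 4, 6, "T", (7.0, 0.0, 0.0)),
        ]
        assert build(segs).graph.edges == frozenset([(1, 2)])

    def test_equilateral_triangle_is_complete(self):
        # all pairwise distances equal the mean: inclusive rule keeps them
        pts = [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.5, math.sqrt(3) / 2, 0.0)]
        segs = [SSERecord("A", i + 1, i + 1, "H", p) for i, p in enumerate(pts)]
        assert build(segs).graph.m == 3

    def test_geometry_consistent_with_representatives(self):
        pg = build(square_segments())
        pts = np.array([s.representative for s in pg.segments])
        for (i, j) in pg.graph.edges:
            assert pg.graph.length(i, j) == pytest.approx(
                np.linalg.norm(pts[i - 1] - pts[j - 1])
            )

    def test_density_monotone_in_threshold_scaling(self):
        rng = np.random.default_rng(5)
        pts = rng.random((10, 3)) * 10
        base = avg_threshold(pts)
        densities = [
            density(Graph.from_points(pts, scale * base))
            for scale in (0.4, 0.7, 1.0, 1.3, 1.8)
        ]
        assert densities == sorted(densities)

    def test_roundtrip_through_files(self, tmp_path):
        pg = build(square_segments())
        edges_path, coords_path = tmp_path / "g.edges", tmp_path / "g.coords"
        io.write_edge_list(pg.graph, edges_path)
        io.write_coordinates(
            np.array([s.representative for s in pg.segments]), coords_path
        )
        back = io.attach_geometry(
            io.read_edge_list(edges_path), io.read_coordinates(coords_path)
        )
        assert back.edges == pg.graph.edges
        np.testing.assert_allclose(back.geometry, pg.graph.geometry, atol=1e-5)


def residue_tsv_text() -> str:
    rows = []
    classes = "HHHHEEEECCC"
    for i, cls in enumerate(classes, start=1):
        angle = i / len(classes) * 2 * math.pi
        x, y, z = 8 * math.cos(angle), 8 * math.sin(angle), 1.5 * i
        rows.append(f"A\t{i}\t{cls}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(rows) + "\n"


class TestResidueInput:
    def test_tsv_reader_and_joint_build(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(residue_tsv_text())
        table = read_residue_tsv(path)
        segs = segments_from_residues(table)
        assert [s.sse_class for s in segs] == ["H", "T", "C"]
        assert (segs[0].start_residue, segs[0].end_residue) == (1, 4)
        pg = build(segs)
        assert pg.graph.n == 3

    def test_per_chain_split(self):
        import pandas as pd

        frames = []
        for chain in ("A", "B"):
            rows = [
                {"chain": chain, "resnum": i, "sse_code": c, "x": float(i), "y": 0.0, "z": 0.0}
                for i, c in enumerate("HHCC", start=1)
            ]
            frames.append(pd.DataFrame(rows))
        table = pd.concat(frames, ignore_index=True)
        by_chain = segments_from_residues(table, per_chain=True)
        assert set(by_chain) == {"A", "B"}
        assert all(len(segs) == 2 for segs in by_chain.values())
        joint = segments_from_residues(table)
        assert len(joint) == 4

    def test_missing_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="lacks columns"):
            segments_from_residues(pd.DataFrame({"chain": ["A"]}))


def dssp_text() -> str:
    """A miniature synthetic DSSP file (header + five residue records)."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  5  1  0  0  0 TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    codes = ["H", "H", "E", " ", "C"]
    lines = []
    for i, code in enumerate(codes, start=1):
        prefix = f"{i:5d}{i:5d} A A  {code}"
        line = prefix.ljust(115) + f"{float(i):7.1f}{0.0:7.1f}{0.0:7.1f}"
        lines.append(line)
    return "\n".join(header + lines) + "\n"


class TestDsspInput:
    def test_fixed_column_parse(self, tmp_path):
        path = tmp_path / "toy.dssp"
        path.write_text(dssp_text())
        table = read_dssp(path)
        assert list(table["resnum"]) == [1, 2, 3, 4, 5]
        assert [classify_sse(c) for c in table["sse_code"]] == ["H", "H", "T", "C", "C"]
        assert list(table["x"]) == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_non_dssp_file_rejected(self, tmp_path):
        path = tmp_path / "not.dssp"
        path.write_text("just some text\n")
        with pytest.raises(ValueError, match="DSSP"):
            read_dssp(path)


PDB_TEMPLATE = (
    "ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


class TestPdbInput:
    def test_ca_extraction(self, tmp_path):
        text = "".join(
            PDB_TEMPLATE.format(serial=i, chain="A", resnum=i, x=float(i), y=0.0, z=0.0)
            for i in range(1, 4)
        ) + "END\n"
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        coords = read_pdb_ca(path)
        assert coords[("A", 2)] == pytest.approx((2.0, 0.0, 0.0))
        assert len(coords) == 3
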