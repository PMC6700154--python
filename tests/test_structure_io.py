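"""Structure parsing, side-chain centers, region labels, radii."""

import numpy as np
import pytest

from mempot.structure_io import (
    AnnotationError,
    EmptyStructureError,
    RadiusTable,
    RegionAnnotation,
    Residue,
    Segment,
    assign_regions,
    compute_side_chain_center,
    default_radius_table,
    estimate_residue_radii,
    parse_structure,
    write_pdb,
)

from conftest import make_structure


def pdb_text(atoms):
    """atoms: list of (record, serial, name, resname, chain, resid, xyz, element)."""
    lines = []
    for rec, serial, name, resname, chain, resid, xyz, element in atoms:
        lines.append(
            f"{rec:<6}{serial:>5} {name:<4} {resname:>3} {chain}{resid:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


GAL_ATOMS = [
    ("ATOM", 1, "N", "GLY", "A", 1, (0.0, 1.0, 0.0), "N"),
    ("ATOM", 2, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C"),
    ("ATOM", 3, "C", "GLY", "A", 1, (1.0, 0.0, 0.0), "C"),
    ("ATOM", 4, "O", "GLY", "A", 1, (1.5, 1.0, 0.0), "O"),
    ("ATOM", 5, "N", "ALA", "A", 2, (2.0, 0.0, 0.0), "N"),
    ("ATOM", 6, "CA", "ALA", "A", 2, (3.0, 0.0, 0.0), "C"),
    ("ATOM", 7, "C", "ALA", "A", 2, (4.0, 0.0, 0.0), "C"),
    ("ATOM", 8, "CB", "ALA", "A", 2, (1.0, 2.0, 3.0), "C"),
    ("ATOM", 9, "N", "LEU", "A", 3, (5.0, 0.0, 0.0), "N"),
    ("ATOM", 10, "CA", "LEU", "A", 3, (6.0, 0.0, 0.0), "C"),
    ("ATOM", 11, "C", "LEU", "A", 3, (7.0, 0.0, 0.0), "C"),
    ("ATOM", 12, "CB", "LEU", "A", 3, (6.0, 1.0, 0.0), "C"),
    ("ATOM", 13, "CG", "LEU", "A", 3, (6.0, 2.0, 0.0), "C"),
    ("ATOM", 14, "CD1", "LEU", "A", 3, (5.0, 3.0, 0.0), "C"),
    ("ATOM", 15, "CD2", "LEU", "A", 3, (7.0, 3.0, 0.0), "C"),
]


class TestParseStructure:
    def test_three_residue_chain(self):
        st = parse_structure(pdb_text(GAL_ATOMS), "gal")
        assert [r.aa for r in st.residues] == ["G", "A", "L"]
        assert [r.seq_index for r in st.residues] == [1, 2, 3]
        # Gly center = CA; Ala center = its lone CB; Leu = side-chain centroid
        np.testing.assert_allclose(st.residues[0].center, (0, 0, 0), atol=1e-6)
        np.testing.assert_allclose(st.residues[1].center, (1, 2, 3), atol=1e-6)
        np.testing.assert_allclose(st.residues[2].center, (6, 2.25, 0), atol=1e-6)

    def test_selenomethionine_maps_to_met(self):
        atoms = [
            ("HETATM", 1, "N", "MSE", "A", 1, (0.0, 0.0, 0.0), "N"),
            ("HETATM", 2, "CA", "MSE", "A", 1, (1.0, 0.0, 0.0), "C"),
            ("HETATM", 3, "CB", "MSE", "A", 1, (2.0, 0.0, 0.0), "C"),
            ("HETATM", 4, "SE", "MSE", "A", 1, (4.0, 0.0, 0.0), "SE"),
            ("ATOM", 5, "N", "ALA", "A", 2, (5.0, 0.0, 0.0), "N"),
            ("ATOM", 6, "CA", "ALA", "A", 2, (6.0, 0.0, 0.0), "C"),
            ("ATOM", 7, "CB", "ALA", "A", 2, (7.0, 0.0, 0.0), "C"),
        ]
        st = parse_structure(pdb_text(atoms), "mse")
        assert st.residues[0].aa == "M"
        # independent hand parse: side-chain atoms CB and SE
        np.testing.assert_allclose(st.residues[0].center, (3.0, 0.0, 0.0), atol=1e-6)

    def test_two_chains_restart_numbering(self):
        atoms = [
            ("ATOM", 1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
            ("ATOM", 2, "CB", "ALA", "A", 1, (1.0, 0.0, 0.0), "C"),
            ("ATOM", 3, "CA", "GLY", "A", 2, (2.0, 0.0, 0.0), "C"),
            ("ATOM", 4, "CA", "ALA", "B", 5, (10.0, 0.0, 0.0), "C"),
            ("ATOM", 5, "CB", "ALA", "B", 5, (11.0, 0.0, 0.0), "C"),
            ("ATOM", 6, "CA", "GLY", "B", 6, (12.0, 0.0, 0.0), "C"),
        ]
        st = parse_structure(pdb_text(atoms), "2ch")
        assert [(r.chain_id, r.seq_index) for r in st.residues] == [
            ("A", 1), ("A", 2), ("B", 1), ("B", 2)
        ]

    def test_unparseable_and_empty(self):
        with pytest.raises(EmptyStructureError):
            parse_structure(pdb_text([
                ("HETATM", 1, "O", "HOH", "A", 1, (0.0, 0.0, 0.0), "O"),
            ]), "wat")


class TestSideChainCenter:
    def test_single_atom_and_conventions(self):
        assert np.allclose(
            compute_side_chain_center([("CB", (1, 2, 3))], aa="A"), (1, 2, 3)
        )
        assert np.allclose(
            compute_side_chain_center([("CA", (0, 0, 0))], aa="G"), (0, 0, 0)
        )

    def test_symmetric_ring(self):
        ring = [
            ("CG", (3, 0, 0)), ("CD1", (2.5, 0.87, 0)), ("CD2", (2.5, -0.87, 0)),
            ("CE1", (1.5, 0.87, 0)), ("CE2", (1.5, -0.87, 0)), ("CZ", (1, 0, 0)),
        ]
        assert np.allclose(compute_side_chain_center(ring, aa="F"), (2, 0, 0))

    def test_missing_side_chain_falls_back_to_ca(self):
        c = compute_side_chain_center([("CA", (5, 5, 5)), ("N", (4, 5, 5))], aa="K")
        assert np.allclose(c, (5, 5, 5))

    def test_no_heavy_atoms_errors(self):
        with pytest.raises(ValueError):
            compute_side_chain_center([("HA", (0, 0, 0))], aa="A")


class TestAssignRegions:
    def _chain(self, n=40):
        return make_structure(
            [("A", "A", (i * 3.8, 0, 0), "UNASSIGNED") for i in range(n)]
        )

    def test_segment_application_and_em_default(self):
        ann = RegionAnnotation([Segment("TEST", "A", 5, 25, "TM")])
        st = assign_regions(self._chain(), ann)
        regions = [r.region for r in st.residues]
        assert regions[4:25] == ["TM"] * 21
        assert all(r == "EM" for r in regions[:4] + regions[25:])
        assert st.region_counts() == {"TM": 21, "EM": 19}

    def test_two_tm_segments_make_three_em_stretches(self):
        ann = RegionAnnotation([
            Segment("TEST", "A", 5, 12, "TM"),
            Segment("TEST", "A", 20, 27, "TM"),
        ])
        st = assign_regions(self._chain(), ann)
        labels = "".join("T" if r.region == "TM" else "E" for r in st.residues)
        import re
        assert len(re.findall("T+", labels)) == 2
        assert len(re.findall("E+", labels)) == 3

    def test_idempotent_and_count_conserving(self):
        ann = RegionAnnotation([Segment("TEST", "A", 5, 25, "TM")])
        once = assign_regions(self._chain(), ann)
        twice = assign_regions(once, ann)
        assert [r.region for r in once.residues] == [r.region for r in twice.residues]
        counts = once.region_counts()
        assert counts.get("TM", 0) + counts.get("EM", 0) == len(once.residues)

    def test_strict_mode_empty_annotation_errors(self):
        with pytest.raises(AnnotationError):
            assign_regions(self._chain(), RegionAnnotation([]), strict=True)

    def test_overlapping_segments_error(self):
        ann = RegionAnnotation([
            Segment("TEST", "A", 5, 15, "TM"),
            Segment("TEST", "A", 10, 20, "TM"),
        ])
        with pytest.raises(AnnotationError):
            assign_regions(self._chain(), ann)

    def test_missing_chain_error(self):
        ann = RegionAnnotation([Segment("TEST", "Z", 1, 5, "TM")])
        with pytest.raises(AnnotationError):
            assign_regions(self._chain(), ann)

    def test_tsv_round_trip(self):
        ann = RegionAnnotation([
            Segment("X", "A", 3, 9, "TM"),
            Segment("X", "A", 10, 14, "EM", "intracellular"),
        ])
        again = RegionAnnotation.from_tsv(ann.to_tsv())
        assert again.records == ann.records


def test_write_parse_round_trip_preserves_centers(small_dataset):
    st = small_dataset.structures[0]
    again = parse_structure(write_pdb(st), st.structure_id)
    assert len(again) == len(st)
    for a, b in zip(st.residues, again.residues):
        assert a.aa == b.aa
        np.testing.assert_allclose(a.center, b.center, atol=1e-3)


class TestResidueRadii:
    def _res(self, aa, atoms):
        return Residue("A", 1, aa, atoms[0][1], atoms=[(n, np.array(x, float)) for n, x in atoms])

    def test_single_atom_and_gly_are_zero(self):
        from mempot.structure_io import LabeledStructure

        ala = self._res("A", [("CB", (1.0, 0, 0)), ("CA", (0.0, 0, 0))])
        gly = self._res("G", [("CA", (0.0, 0, 0))])
        st = LabeledStructure("r", [ala, gly])
        table = estimate_residue_radii([st])
        assert table["A"] == 0.0
        assert table["G"] == 0.0

    def test_ring_radius_matches_hand_value(self):
        from mempot.structure_io import LabeledStructure

        # hexagon of radius 1.4 about (2, 0, 0)
        ring = []
        for k in range(6):
            a = 2 * np.pi * k / 6
            ring.append((f"C{k}", (2 + 1.4 * np.cos(a), 1.4 * np.sin(a), 0.0)))
        phe = self._res("F", ring + [("CA", (0.0, 0, 0))])
        pad = self._res("A", [("CB", (9.0, 0, 0))])
        table = estimate_residue_radii([LabeledStructure("r", [phe, pad])])
        assert table["F"] == pytest.approx(1.4, abs=1e-9)

    def test_missing_types_fall_back_to_defaults(self):
        from mempot.structure_io import LabeledStructure

        ala = self._res("A", [("CB", (1.0, 0, 0))])
        st = LabeledStructure("r", [ala, self._res("G", [("CA", (5.0, 0, 0))])])
        table = estimate_residue_radii([st])
        defaults = default_radius_table()
        assert table["W"] == defaults["W"]
        assert table["W"] > table["A"]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            estimate_residue_radii([])

    def test_radius_table_validation(self):
        with pytest.raises(ValueError):
            RadiusTable({"A": 1.0})  # missing types
        bad = dict(default_radius_table().radii)
        bad["G"] = 0.5
        with pytest.raises(ValueError):
            RadiusTable(bad)
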