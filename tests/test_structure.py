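import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import quaternion_superpose_rmsd
from qtycode.seqio import ProteinRecord, Segment, SegmentAnnotation
from qtycode.structure import (
    Atom,
    HelixSpec,
    StructureError,
    StructureModel,
    build_bundle,
    build_ideal_helix,
    helix_geometry,
    kabsch_superpose,
    match_residues,
    parse_pdb,
    superpose_models,
    trim_to_segments,
    write_pdb,
)

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.000   7.460  -4.629  1.00  0.00           C
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BBLE A   1       2.000   0.000   0.000  0.60  0.00           C
END
"""


def rotation_matrix(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = math.radians(deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


class TestParsePdb:
    def test_three_atoms_exact(self):
        model = parse_pdb(PDB_3ATOMS)
        assert len(model) == 3
        ca = model.atoms[1]
        assert (ca.x, ca.y, ca.z) == (11.639, 6.071, -5.147)
        assert ca.atom_name == "CA"
        assert ca.element == "C"
        assert ca.residue_name == "ALA"

    def test_altloc_highest_occupancy_wins(self):
        model = parse_pdb(PDB_ALTLOC)
        assert len(model) == 1
        assert model.atoms[0].x == 2.000

    def test_altloc_tie_prefers_a(self):
        text = PDB_ALTLOC.replace("0.40", "0.60")
        model = parse_pdb(text)
        assert model.atoms[0].x == 1.000

    def test_empty_file(self):
        with pytest.raises(StructureError, match="no ATOM records"):
            parse_pdb("END\n")

    def test_malformed_coordinate_reports_line(self):
        bad = PDB_3ATOMS.replace("11.639", "xx.xxx")
        with pytest.raises(StructureError, match="line 2"):
            parse_pdb(bad)

    def test_hetatm_ignored_by_default(self):
        text = PDB_3ATOMS.replace("ATOM      3", "HETATM    3")
        assert len(parse_pdb(text)) == 2

    def test_model_selection(self):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       9.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        assert parse_pdb(text, model_index=0).atoms[0].x == 1.0
        assert parse_pdb(text, model_index=1).atoms[0].x == 9.0

    def test_write_parse_round_trip(self):
        helix = build_ideal_helix(HelixSpec(12))
        back = parse_pdb(write_pdb(helix))
        assert len(back) == 12
        np.testing.assert_allclose(back.coords(), helix.coords(), atol=1e-3)


class TestMatchResidues:
    @staticmethod
    def chain_model(resids, chain="A", model_id="m"):
        atoms = tuple(
            Atom(chain, r, "ALA", "CA", "C", float(r), 0.0, 0.0) for r in resids
        )
        return StructureModel(model_id=model_id, atoms=atoms)

    def test_interval_intersection(self):
        a = self.chain_model(range(1, 11))
        b = self.chain_model(range(5, 16), model_id="m2")
        pairs = match_residues(a, b)
        assert [p.residue_seq for p in pairs] == [5, 6, 7, 8, 9, 10]

    def test_disjoint_numbering(self):
        a = self.chain_model(range(1, 5))
        b = self.chain_model(range(10, 15), model_id="m2")
        with pytest.raises(StructureError, match="no common residues"):
            match_residues(a, b)

    def test_missing_ca_excluded(self):
        a = self.chain_model([1, 2, 3])
        atoms = (
            Atom("A", 1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
            Atom("A", 2, "ALA", "CB", "C", 0.0, 0.0, 0.0),  # no CA for residue 2
            Atom("A", 3, "ALA", "CA", "C", 0.0, 0.0, 0.0),
        )
        b = StructureModel(model_id="m2", atoms=atoms)
        pairs = match_residues(a, b)
        assert [p.residue_seq for p in pairs] == [1, 3]


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(20, 3))
        rot = rotation_matrix([0, 0, 1], 37.0)
        mobile = ref @ rot.T + np.array([5.0, -2.0, 9.0])
        sup = kabsch_superpose(ref, mobile)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(StructureError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(StructureError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_quaternion_oracle_hundred_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            ref = rng.normal(scale=5.0, size=(n, 3))
            mob = rng.normal(scale=5.0, size=(n, 3))
            sup = kabsch_superpose(ref, mob)
            _, oracle_rmsd = quaternion_superpose_rmsd(ref, mob)
            assert sup.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_mirror_input_still_proper_rotation(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(15, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        sup = kabsch_superpose(ref, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)
        assert sup.rmsd > 0.0

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(-180.0, 180.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_rmsd_invariant_under_rigid_motion(self, seed, angle, shift):
        rng = np.random.default_rng(seed)
        ref = rng.normal(scale=3.0, size=(12, 3))
        mob = rng.normal(scale=3.0, size=(12, 3))
        base = kabsch_superpose(ref, mob).rmsd
        rot = rotation_matrix([1, 2, 3], angle)
        moved = mob @ rot.T + shift
        assert kabsch_superpose(ref, moved).rmsd == pytest.approx(base, abs=1e-6)


class TestTrim:
    def test_keeps_tm_residues_only(self):
        atoms = tuple(
            Atom("A", r, "ALA", "CA", "C", float(r), 0.0, 0.0)
            for r in range(1, 101)
        )
        model = StructureModel(model_id="m", atoms=atoms)
        ann = SegmentAnnotation(
            "m",
            (Segment("TM1", 10, 30, "TM"), Segment("TM2", 40, 60, "TM")),
        )
        trimmed = trim_to_segments(model, ann)
        kept = {a.residue_seq for a in trimmed.atoms}
        assert kept == set(range(10, 31)) | set(range(40, 61))
        assert len(trimmed) <= len(model)

    def test_empty_result_errors(self):
        atoms = (Atom("A", 1, "ALA", "CA", "C", 0.0, 0.0, 0.0),)
        model = StructureModel(model_id="m", atoms=atoms)
        ann = SegmentAnnotation("m", (Segment("TM1", 50, 60, "TM"),))
        with pytest.raises(StructureError, match="no atoms"):
            trim_to_segments(model, ann)


class TestIdealHelix:
    def test_axial_extent(self):
        helix = build_ideal_helix(HelixSpec(36))
        z = helix.coords()[:, 2]
        assert z.max() - z.min() == pytest.approx(35 * 1.5, abs=1e-9)

    def test_geometry_recovered_after_axis_fit(self):
        geo = helix_geometry(build_ideal_helix(HelixSpec(36)))
        assert geo["rise_per_residue"] == pytest.approx(1.5, abs=1e-2)
        assert geo["twist_per_residue"] == pytest.approx(100.0, abs=0.1)
        assert geo["residues_per_turn"] == pytest.approx(3.6, abs=1e-2)
        assert geo["pitch"] == pytest.approx(5.4, abs=1e-2)

    def test_geometry_invariant_under_rigid_motion(self):
        helix = build_ideal_helix(HelixSpec(30))
        rot = rotation_matrix([1, 1, 0], 63.0)
        moved_atoms = []
        for a in helix.atoms:
            p = rot @ np.array([a.x, a.y, a.z]) + np.array([3.0, -7.0, 11.0])
            moved_atoms.append(a._replace(x=p[0], y=p[1], z=p[2]))
        geo = helix_geometry(StructureModel("moved", tuple(moved_atoms)))
        assert geo["rise_per_residue"] == pytest.approx(1.5, abs=1e-2)
        assert geo["pitch"] == pytest.approx(5.4, abs=1e-2)

    def test_ca_spacing_constant(self):
        helix = build_ideal_helix(HelixSpec(20))
        pts = helix.coords()
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert d.std() == pytest.approx(0.0, abs=1e-9)

    def test_minimum_length(self):
        with pytest.raises(StructureError):
            HelixSpec(3)


class TestBundle:
    def test_atom_count(self):
        bundle = build_bundle(7, HelixSpec(26), 10.0)
        assert len(bundle) == 7 * 26

    def test_pair_fixture_count(self):
        bundle = build_bundle(7, HelixSpec(22), 10.0)
        assert len(bundle) == 154

    def test_helix_centroids_balanced(self):
        bundle = build_bundle(7, HelixSpec(22), 10.0)
        pts = bundle.coords()
        centroids = pts.reshape(7, 22, 3).mean(axis=1)
        # helix axis centres are exactly balanced; per-helix centroids carry a
        # small shared phase offset (22 residues is not a whole turn number)
        np.testing.assert_allclose(centroids.mean(axis=0)[:2], 0.0, atol=0.1)

    def test_superpose_rigid_copy_rmsd_zero(self):
        bundle = build_bundle(7, HelixSpec(22), 10.0)
        rot = rotation_matrix([0, 1, 0], 24.0)
        moved_atoms = tuple(
            a._replace(
                x=float((rot @ a.position)[0] + 1.0),
                y=float((rot @ a.position)[1] - 2.0),
                z=float((rot @ a.position)[2] + 3.0),
            )
            for a in bundle.atoms
        )
        moved = StructureModel("copy", moved_atoms)
        sup, transformed = superpose_models(bundle, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert sup.n_matched == 154

    def test_sequence_labels_follow_annotation(self, synth_pair, bundles):
        record, annotation, result = synth_pair
        native, variant = bundles
        seg = annotation.tm_segments[0]
        first = native.atoms[0]
        assert first.residue_seq == seg.start
        from qtycode.structure import THREE_TO_ONE

        assert THREE_TO_ONE[first.residue_name] == record.sequence[seg.start - 1]
        # coordinates identical between native and variant
        np.testing.assert_allclose(native.coords(), variant.coords(), atol=0)
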