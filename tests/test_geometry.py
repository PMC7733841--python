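import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import axialfil as af
from axialfil.geometry import SelectorError, kabsch, sequence_identity_all_conventions
from axialfil.synthetic import toy_triad_ids


def ring_fixture(donor_pos):
    """His ring at hand-placed coordinates plus a donor atom."""
    ring = {
        "CG": (0.0, 0.0, 0.0),
        "ND1": (0.14, 0.0, 0.0),
        "CD2": (-0.05, 0.13, 0.0),
        "CE1": (0.18, 0.13, 0.0),
        "NE2": (0.06, 0.21, 0.0),
    }
    atoms = [af.Atom("N" if k.startswith("N") else "C", k, "HIS", 165, "A", v) for k, v in ring.items()]
    atoms.append(af.Atom("O", "OG", "SER", 26, "A", donor_pos))
    return af.AtomicModel.from_atoms(atoms), ring


class TestRingDistance:
    def test_hand_computed_minimum(self):
        model, ring = ring_fixture((0.3, 0.3, 0.1))
        expected = min(np.linalg.norm(np.array((0.3, 0.3, 0.1)) - np.array(v)) for v in ring.values())
        d = af.min_ring_distance(model, ("A", 26, "OG"), ("A", 165))
        assert d == pytest.approx(expected * 10.0, abs=1e-9)

    def test_donor_on_ring_atom_gives_zero(self):
        model, _ = ring_fixture((0.14, 0.0, 0.0))
        assert af.min_ring_distance(model, ("A", 26, "OG"), ("A", 165)) == pytest.approx(0.0)

    def test_unresolvable_selector_names_selector(self):
        model, _ = ring_fixture((0.3, 0.3, 0.1))
        with pytest.raises(SelectorError, match="B/26/OG"):
            af.min_ring_distance(model, ("B", 26, "OG"), ("A", 165))

    def test_planted_triad_distances(self, toy_model):
        ids = toy_triad_ids(af.ToyCrystalSpec(seed=1, include_triad=True))
        d = af.min_ring_distance(toy_model, ("A", ids["SER"], "OG"), ("A", ids["HIS"]))
        assert d == pytest.approx(3.6, abs=1e-6)
        tg = af.triad_geometry(toy_model, ("A", ids["SER"]), ("A", ids["HIS"]))
        assert tg.ser_og_to_his_ring <= tg.ser_og_to_his_ne2 + 1e-12


@pytest.fixture(scope="module")
def triad_ids():
    return toy_triad_ids(af.ToyCrystalSpec(seed=1, include_triad=True))


class TestChi1Scan:

    def test_zero_rotation_matches_unrotated(self, toy_model, triad_ids):
        scan = af.scan_chi1(toy_model, ("A", triad_ids["SER"]), ("A", triad_ids["HIS"]), step=360.0)
        d0 = af.min_ring_distance(toy_model, ("A", triad_ids["SER"], "OG"), ("A", triad_ids["HIS"]))
        assert scan.distances[0] == pytest.approx(d0, abs=1e-9)

    def test_scan_finds_planted_minimum(self, toy_model, triad_ids):
        scan = af.scan_chi1(toy_model, ("A", triad_ids["SER"]), ("A", triad_ids["HIS"]), step=1.0)
        assert scan.best_distance == pytest.approx(2.9, abs=0.01)

    def test_fine_scan_dominates_coarse(self, toy_model, triad_ids):
        fine = af.scan_chi1(toy_model, ("A", triad_ids["SER"]), ("A", triad_ids["HIS"]), step=1.0)
        coarse = af.scan_chi1(toy_model, ("A", triad_ids["SER"]), ("A", triad_ids["HIS"]), step=10.0)
        assert fine.best_distance <= coarse.distances.min() + 1e-12

    def test_internal_geometry_preserved(self, toy_model, triad_ids):
        sid = triad_ids["SER"]
        sel = lambda name: toy_model.xyz[
            (toy_model.chain_id == "A") & (toy_model.res_id == sid) & (toy_model.name == name)
        ][0]
        ca, cb, og = sel("CA"), sel("CB"), sel("OG")
        bond = np.linalg.norm(og - cb)
        cosang = np.dot(ca - cb, og - cb) / (np.linalg.norm(ca - cb) * bond)
        from axialfil.geometry import _rodrigues

        for ang in (37.0, 123.0, 301.0):
            R = _rodrigues(cb - ca, np.deg2rad(ang))
            og_rot = cb + R @ (og - cb)
            assert np.linalg.norm(og_rot - cb) == pytest.approx(bond, abs=1e-8)
            cos2 = np.dot(ca - cb, og_rot - cb) / (np.linalg.norm(ca - cb) * bond)
            assert np.arccos(cos2) == pytest.approx(np.arccos(cosang), abs=1e-6)

    def test_missing_atoms_raise(self, toy_model, triad_ids):
        with pytest.raises(SelectorError):
            af.scan_chi1(toy_model, ("A", 1), ("A", triad_ids["HIS"]))  # ALA has no OG


class TestSuperposition:
    def test_self_superposition_zero(self, toy_model):
        res = af.superpose_calpha(toy_model, toy_model, matching="resnum")
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.n_matched == int(np.sum(toy_model.name == "CA"))

    def test_recovers_planted_rigid_transform(self):
        a, b, R_true = af.make_calpha_pair(n_residues=60, rms_noise=0.0, n_outliers=0, seed=3)
        res = af.superpose_calpha(a, b, matching="resnum")
        assert res.rmsd < 1e-6
        assert np.allclose(res.rotation, R_true, atol=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_equals_rms_of_pair_deviations(self):
        a, b, _ = af.make_calpha_pair(n_residues=80, rms_noise=1.0, n_outliers=0, seed=5)
        res = af.superpose_calpha(a, b)
        assert res.rmsd == pytest.approx(np.sqrt(np.mean(res.per_pair_deviations**2)), rel=1e-12)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        a, b, _ = af.make_calpha_pair(n_residues=60, rms_noise=0.8, n_outliers=0, seed=9)
        base = af.superpose_calpha(a, b).rmsd
        R = Rotation.from_euler("zyx", [0.3, -1.0, 2.2]).as_matrix()
        a2 = a.with_(xyz=a.xyz @ R.T + np.array([1.0, -2.0, 0.5]))
        assert af.superpose_calpha(a2, b).rmsd == pytest.approx(base, abs=1e-8)

    def test_kabsch_agrees_with_scipy(self, rng):
        P = rng.normal(size=(40, 3))
        R_true = Rotation.from_rotvec([0.4, -0.2, 1.1]).as_matrix()
        Q = P @ R_true.T + np.array([0.3, 0.7, -1.2])
        R, t = kabsch(P, Q)
        R_scipy, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(R, R_scipy.as_matrix(), atol=1e-8)
        assert np.allclose(P @ R.T + t, Q, atol=1e-10)

    def test_trimming_emulates_divergent_loops(self):
        a, b, _ = af.make_calpha_pair(seed=4)  # 218 residues, 19 outliers
        res = af.superpose_calpha(a, b, matching="sequence", trim_threshold=2.0)
        assert res.n_matched == pytest.approx(199, abs=10)
        assert res.rmsd == pytest.approx(0.67, abs=0.1)

    def test_too_few_pairs_raise(self):
        a, b, _ = af.make_calpha_pair(n_residues=2, rms_noise=0.0, n_outliers=0, seed=0)
        with pytest.raises(ValueError):
            af.superpose_calpha(a, b)


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert af.sequence_identity("ACDEFGHIKL", "ACDEFGHIKL") == pytest.approx(100.0)

    def test_three_of_four(self):
        assert af.sequence_identity("ACDE", "ACDF") == pytest.approx(75.0)

    def test_symmetric_and_bounded(self):
        sa, sb = af.make_sequence_pair(length=120, identity_pct=60.0, seed=2)
        ab = af.sequence_identity(sa, sb)
        ba = af.sequence_identity(sb, sa)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert 0.0 <= ab <= 100.0

    def test_planted_identity_recovered(self):
        sa, sb = af.make_sequence_pair(length=218, identity_pct=52.0, seed=11)
        assert af.sequence_identity(sa, sb) == pytest.approx(52.0, abs=1.0)

    def test_all_conventions_reported(self):
        out = sequence_identity_all_conventions("ACDEFGHIKL", "CDEFGHIK")
        assert set(out) == {"core_columns", "all_columns", "shorter"}

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            af.sequence_identity("ACDX1", "ACDEF")
        with pytest.raises(ValueError):
            af.sequence_identity("", "ACDEF")
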