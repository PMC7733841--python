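import numpy as np
import pytest

import axialfil as af
from axialfil.structio import GeometryError
from axialfil.symmetry import min_interchain_distance


class TestOperators:
    def test_p3121_has_six_ops_identity_first(self, p3121):
        assert p3121.multiplicity == 6
        assert np.array_equal(p3121.ops[0].R, np.eye(3))
        assert np.allclose(p3121.ops[0].t, 0)

    def test_ops_match_gemmi_reference(self, p3121):
        gemmi = pytest.importorskip("gemmi")
        ref = {op.triplet().replace(" ", "") for op in gemmi.SpaceGroup("P 31 2 1").operations()}
        ours = {op.triplet().replace("+", "", 1) if op.triplet().startswith("+") else op.triplet() for op in p3121.ops}
        # normalize: strip leading '+' on each coordinate expression
        def norm(t):
            return ",".join(p.lstrip("+") for p in t.split(","))
        assert {norm(t) for t in ours} == {norm(t) for t in ref}

    def test_composition_closes_modulo_lattice(self, p3121):
        keys = {(tuple(map(tuple, op.rotation)), tuple(float(x) % 1 for x in op.t)) for op in p3121.ops}
        for a in p3121.ops:
            for b in p3121.ops:
                c = a.compose(b)
                key = (tuple(map(tuple, c.rotation)), tuple(float(x) % 1 for x in c.t))
                assert key in keys

    @pytest.mark.parametrize(
        "op_idx,frac,expected",
        [
            (0, (0.1, 0.2, 0.3), (0.1, 0.2, 0.3)),
            (1, (0.1, 0.2, 0.3), (0.8, 0.9, 0.3 + 1.0 / 3.0)),  # -y, x-y, z+1/3 wrapped
            (3, (0.1, 0.2, 0.3), (0.2, 0.1, 0.7)),  # y, x, -z wrapped
        ],
    )
    def test_apply_symop_hand_values(self, p3121, op_idx, frac, expected):
        assert af.apply_symop(p3121.ops[op_idx], frac) == pytest.approx(expected)

    def test_unsupported_group_lists_supported(self):
        with pytest.raises(ValueError, match="P3121"):
            af.get_space_group("P212121")

    def test_p1_single_operator(self):
        assert af.get_space_group("P1").multiplicity == 1


class TestExpansion:
    def test_general_position_multiplicity_six(self, p3121):
        cell = af.UnitCell(2, 2, 4, 90, 90, 120)
        frac0 = np.array([0.137, 0.291, 0.053])
        orbit = np.array([af.apply_symop(op, frac0) for op in p3121.ops])
        d = orbit[:, None, :] - orbit[None, :, :]
        d -= np.round(d)
        off_diag = ~np.eye(6, dtype=bool)
        assert np.all(np.linalg.norm(d[off_diag], axis=-1) > 1e-6)

    def test_expand_multiplies_atom_count(self, toy_model, toy_expanded, p3121):
        assert len(toy_expanded) == len(toy_model) * 6
        assert toy_expanded.space_group_name == "P1"
        assert len(np.unique(toy_expanded.chain_id)) == 6

    def test_expand_under_p1_is_identity(self, toy_model):
        out = af.expand_to_p1(toy_model, af.get_space_group("P1"))
        assert len(out) == len(toy_model)
        assert np.allclose(out.xyz, toy_model.xyz)

    def test_expanded_point_set_invariant_under_group(self, toy_expanded, p3121):
        frac = toy_expanded.frac() % 1.0
        for op in p3121.ops:
            moved = op.apply(frac) % 1.0
            d = moved[:, None, :] - frac[None, :, :]
            d -= np.round(d)
            nearest = np.linalg.norm(d, axis=-1).min(axis=1)
            assert nearest.max() < 1e-6

    def test_expand_requires_cell(self, toy_model, p3121):
        with pytest.raises(GeometryError):
            af.expand_to_p1(toy_model.with_(cell=None), p3121)

    def test_molecules_kept_whole(self, toy_expanded):
        # within each chain, atoms stay contiguous (no atom wrapped across
        # the cell alone): max intra-chain extent stays molecular
        for cid in np.unique(toy_expanded.chain_id):
            sub = toy_expanded.xyz[toy_expanded.chain_id == cid]
            assert np.ptp(sub, axis=0).max() < 1.5  # nm; molecule-sized


class TestSupercell:
    def test_identity_supercell(self, toy_expanded):
        out = af.build_supercell(toy_expanded, 1, 1, 1)
        assert len(out) == len(toy_expanded)
        assert out.cell.a == toy_expanded.cell.a

    def test_thickness_supercell_geometry(self):
        # 6 cells of c = 11.63 nm reach 69.78 nm, the nearest achievable to 70
        cell = af.UnitCell(5.96, 5.96, 11.63, 90, 90, 120)
        n = round(70.0 / cell.c)
        assert n == 6
        model = af.AtomicModel.from_atoms(
            [af.Atom("C", "C1", "UNK", 1, "A", (0.5, 0.5, 0.5))], cell=cell, space_group_name="P1"
        )
        out = af.build_supercell(model, 1, 1, n)
        assert out.cell.c == pytest.approx(69.78)
        assert len(out) == 6

    def test_inplane_replication_scales(self, toy_expanded):
        out = af.build_supercell(toy_expanded, 2, 2, 1)
        assert len(out) == 4 * len(toy_expanded)
        assert out.cell.a == pytest.approx(2 * toy_expanded.cell.a)
        assert out.cell.b == pytest.approx(2 * toy_expanded.cell.b)

    def test_nonpositive_counts_rejected(self, toy_expanded):
        with pytest.raises(ValueError):
            af.build_supercell(toy_expanded, 0, 1, 1)


def test_toy_symmetry_copies_do_not_clash(toy_expanded):
    assert min_interchain_distance(toy_expanded) > 0.1
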