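"""Lattice construction and CoMFA/CoMSIA field evaluation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from trpa1_qsar import fields as f

from conftest import toy_conformer


def _point_index(grid, point):
    """Flat index of a lattice point in the x-fastest enumeration."""
    idx = np.round((np.asarray(point) - np.asarray(grid.origin)) / grid.spacing).astype(int)
    nx, ny, _ = grid.dims
    return idx[0] + nx * (idx[1] + ny * idx[2])


class TestMakeGrid:
    def test_single_atom_margin4_spacing1_gives_729_points(self):
        grid = f.make_grid([toy_conformer([[0, 0, 0]])], spacing=1.0, margin=4.0)
        assert grid.dims == (9, 9, 9)
        assert grid.n_points == 729
        assert grid.origin == (-4.0, -4.0, -4.0)

    def test_zero_margin_box_equals_bounding_box(self):
        conf = toy_conformer([[0, 0, 0], [2, 3, 1]])
        grid = f.make_grid([conf], spacing=1.0, margin=0.0)
        assert grid.origin == (0.0, 0.0, 0.0)
        assert grid.dims == (3, 4, 2)

    def test_grid_is_invariant_to_conformer_order(self):
        rng = np.random.default_rng(0)
        confs = [toy_conformer(rng.normal(0, 3, (5, 3))) for _ in range(6)]
        a = f.make_grid(confs)
        b = f.make_grid(confs[::-1])
        assert a == b

    def test_all_atoms_at_least_margin_inside(self):
        rng = np.random.default_rng(1)
        confs = [toy_conformer(rng.normal(0, 3, (5, 3))) for _ in range(4)]
        grid = f.make_grid(confs, spacing=1.0, margin=4.0)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        coords = np.vstack([c.coords for c in confs])
        assert (coords - lo >= 4.0 - 1e-9).all()
        assert (hi - coords >= 4.0 - 1e-9).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            f.make_grid([])
        with pytest.raises(ValueError):
            f.make_grid([toy_conformer([[0, 0, 0]])], spacing=0.0)


class TestComfaSteric:
    def test_far_point_energy_negligible(self):
        conf = toy_conformer([[0, 0, 0]])
        grid = f.GridSpec(origin=(16.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert abs(f.comfa_steric(conf, grid)[0]) < 1e-3

    def test_probe_on_atom_clamps_to_plus_30(self):
        conf = toy_conformer([[0, 0, 0]])
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comfa_steric(conf, grid)[0] == 30.0

    def test_lj_minimum_is_minus_epsilon_at_r_star(self):
        # carbon atom vs sp3 carbon probe: R* = 3.4 A, eps = 0.107
        conf = toy_conformer([[0, 0, 0]])
        grid = f.GridSpec(origin=(3.4, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comfa_steric(conf, grid)[0] == pytest.approx(-0.107, abs=1e-10)

    def test_energies_bounded_by_truncation(self):
        rng = np.random.default_rng(2)
        conf = toy_conformer(rng.normal(0, 2, (10, 3)))
        grid = f.make_grid([conf], spacing=1.0, margin=2.0)
        e = f.comfa_steric(conf, grid)
        assert (e <= 30.0).all() and (e >= -30.0).all()


class TestComfaElectrostatic:
    def test_hand_computed_coulomb_value_clamps(self):
        # q=+1 at 3.32 A with D(r)=r: 332.0636/3.32^2 = 30.12 -> clamped
        conf = toy_conformer([[0, 0, 0]], charges=[1.0])
        grid = f.GridSpec(origin=(3.32, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comfa_electrostatic(conf, grid)[0] == 30.0
        grid2 = f.GridSpec(origin=(4.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comfa_electrostatic(conf, grid2)[0] == pytest.approx(
            332.0636 / 16.0, abs=1e-9
        )

    def test_neutral_atoms_give_zero_field(self):
        conf = toy_conformer(np.random.default_rng(0).normal(0, 2, (5, 3)))
        grid = f.make_grid([conf], spacing=2.0, margin=3.0)
        assert np.all(f.comfa_electrostatic(conf, grid) == 0.0)

    def test_charge_sign_flip_negates_unclamped_field(self):
        rng = np.random.default_rng(3)
        q = rng.normal(0, 0.2, 5)
        conf = toy_conformer(rng.normal(0, 2, (5, 3)), charges=q)
        flipped = toy_conformer(conf.coords, charges=-q)
        grid = f.make_grid([conf], spacing=2.0, margin=4.0)
        a = f.comfa_electrostatic(conf, grid)
        b = f.comfa_electrostatic(flipped, grid)
        unclamped = (np.abs(a) < 30.0) & (np.abs(b) < 30.0)
        np.testing.assert_allclose(a[unclamped], -b[unclamped], atol=1e-10)

    def test_zero_distance_never_crashes(self):
        conf = toy_conformer([[0, 0, 0]], charges=[-1.0])
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comfa_electrostatic(conf, grid)[0] == -30.0


class TestComsia:
    def test_kernel_at_zero_distance(self):
        conf = toy_conformer([[0, 0, 0]], weights={"steric": [1.0]})
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comsia_field(conf, grid, channel="steric")[0] == pytest.approx(-1.0)

    def test_kernel_at_two_angstrom(self):
        conf = toy_conformer([[0, 0, 0]], weights={"steric": [1.0]})
        grid = f.GridSpec(origin=(2.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        assert f.comsia_field(conf, grid, channel="steric")[0] == pytest.approx(
            -np.exp(-0.3 * 4.0), abs=1e-12
        )

    def test_empty_molecule_gives_zeros(self):
        conf = toy_conformer(np.zeros((0, 3)))
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(2, 2, 2), margin=0)
        assert np.all(f.comsia_field(conf, grid, channel="steric") == 0.0)

    def test_unknown_channel_rejected(self):
        conf = toy_conformer([[0, 0, 0]])
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
        with pytest.raises(KeyError):
            f.comsia_field(conf, grid, channel="magnetic")

    def test_all_values_finite_near_atoms(self):
        rng = np.random.default_rng(4)
        conf = toy_conformer(rng.normal(0, 1, (8, 3)))
        grid = f.make_grid([conf], spacing=1.0, margin=2.0)
        for ch in ("steric", "electrostatic", "hydrophobic", "donor", "acceptor"):
            assert np.isfinite(f.comsia_field(conf, grid, channel=ch)).all()

    def test_steric_rankings_anticorrelate_with_lj_near_surface(self):
        # one carbon atom, probes walking up the repulsive wall: LJ energy
        # rises toward the atom while the similarity index becomes more
        # negative, so their ranks anticorrelate
        conf = toy_conformer([[0, 0, 0]], weights={"steric": [1.0]})
        r = np.arange(2.4, 3.31, 0.1)  # repulsive wall, inside the LJ minimum
        lj, cs = [], []
        for d in r:
            g = f.GridSpec(origin=(d, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1), margin=0)
            lj.append(f.comfa_steric(conf, g)[0])
            cs.append(f.comsia_field(conf, g, channel="steric")[0])
        rho = spearmanr(lj, cs).statistic
        assert rho < 0


class TestAssemble:
    def test_shape_and_channel_order(self):
        rng = np.random.default_rng(5)
        confs = [toy_conformer(rng.normal(0, 2, (4, 3)), charges=rng.normal(0, 0.1, 4))
                 for _ in range(3)]
        grid = f.make_grid(confs, spacing=2.0, margin=2.0)
        fm = f.assemble_field_matrix(confs, grid)
        assert fm.values.shape == (3, grid.n_points, 7)
        assert fm.channels == f.ALL_CHANNELS
        assert np.isfinite(fm.values).all()

    def test_translation_of_everything_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(6)
        confs = [toy_conformer(rng.normal(0, 2, (4, 3)), charges=rng.normal(0, 0.1, 4))
                 for _ in range(2)]
        grid = f.make_grid(confs, spacing=1.0, margin=2.0)
        fm1 = f.assemble_field_matrix(confs, grid)
        shift = np.array([3.0, -1.0, 2.0])
        moved = [c.translated(shift) for c in confs]
        grid2 = f.GridSpec(tuple(np.asarray(grid.origin) + shift), grid.spacing,
                           grid.dims, grid.margin)
        fm2 = f.assemble_field_matrix(moved, grid2)
        np.testing.assert_allclose(fm1.values, fm2.values, atol=1e-10)

    def test_atom_order_is_immaterial(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 2, (5, 3))
        q = rng.normal(0, 0.1, 5)
        conf = toy_conformer(coords, charges=q)
        conf_rev = toy_conformer(coords[::-1], charges=q[::-1])
        grid = f.make_grid([conf], spacing=1.0, margin=2.0)
        fm1 = f.assemble_field_matrix([conf], grid)
        fm2 = f.assemble_field_matrix([conf_rev], grid)
        np.testing.assert_allclose(fm1.values, fm2.values, atol=1e-10)

    def test_comfa_channels_respect_truncation_interval(self, pipeline_result):
        res, _ = pipeline_result
        fm = res.field_matrix
        for ch in f.COMFA_CHANNELS:
            block = fm.values[:, :, fm.channels.index(ch)]
            assert block.min() >= -30.0 and block.max() <= 30.0

    def test_electrostatic_mean_fill_at_clamped_points(self):
        # two identical neutral atoms + one charged: where the probe sits on
        # the atoms the electrostatic value equals the mean of the others
        confs = [
            toy_conformer([[0, 0, 0]], charges=[0.5]),
            toy_conformer([[0, 0, 0]], charges=[-0.1]),
            toy_conformer([[5, 0, 0]], charges=[0.2]),
        ]
        grid = f.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(2, 1, 1), margin=0)
        fm = f.assemble_field_matrix(confs, grid, channels=f.COMFA_CHANNELS)
        elec = fm.values[:, :, 1]
        # at point (0,0,0) compounds 1 and 2 are clamped; compound 3 is not
        expected = 332.0636 * 0.2 / 25.0
        assert elec[0, 0] == pytest.approx(expected)
        assert elec[1, 0] == pytest.approx(expected)

    def test_doubling_spacing_keeps_values_at_coincident_points(self):
        conf = toy_conformer([[0.5, 0.5, 0.5]], charges=[0.3])
        g1 = f.GridSpec(origin=(-2.0, -2.0, -2.0), spacing=1.0, dims=(9, 9, 9), margin=0)
        g2 = f.GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(5, 5, 5), margin=0)
        assert g2.n_points * 8 > g1.n_points  # ~8x fewer points at double spacing
        fm1 = f.assemble_field_matrix([conf], g1, channels=("comfa_steric",))
        fm2 = f.assemble_field_matrix([conf], g2, channels=("comfa_steric",))
        for pt in [(-2, -2, -2), (0, 0, 0), (2, 2, 2), (4, -2, 0)]:
            i1 = _point_index(g1, pt)
            i2 = _point_index(g2, pt)
            assert fm1.values[0, i1, 0] == pytest.approx(fm2.values[0, i2, 0], abs=1e-12)


class TestPersistence:
    def test_archive_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        confs = [toy_conformer(rng.normal(0, 2, (3, 3))) for _ in range(2)]
        grid = f.make_grid(confs, spacing=2.0, margin=2.0)
        fm = f.assemble_field_matrix(confs, grid)
        f.save_field_matrix(fm, tmp_path / "fm")
        back = f.load_field_matrix(tmp_path / "fm")
        np.testing.assert_array_equal(fm.values, back.values)
        assert back.channels == fm.channels
        assert back.grid == fm.grid
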