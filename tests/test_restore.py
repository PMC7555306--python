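import numpy as np
import pytest

import saxskit as sk
from saxskit.config import AnnealSchedule

FAST = AnnealSchedule(max_levels=15, moves_per_bead=15, patience=5)


def small_sphere_target():
    m = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=500, radius=20.0), seed=2)
    s = np.linspace(0.002, 0.03, 50)
    i = sk.debye_intensity(m, s)
    return m, sk.ScatteringProfile(s, i, 0.01 * i)


class TestChi2Fit:
    def test_identity(self):
        p = sk.ScatteringProfile([0.01, 0.02, 0.03], [4.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        fit = sk.chi2_fit(p, [4.0, 2.0, 1.0])
        assert fit.k_scale == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-24)

    def test_exact_scaling_absorbed_by_k(self):
        p = sk.ScatteringProfile([0.01, 0.02, 0.03], [4.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        fit = sk.chi2_fit(p, [2.0, 1.0, 0.5])
        assert fit.k_scale == pytest.approx(2.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-24)

    def test_hand_computed_example(self):
        """I_exp=[2,1], I_model=[1,1], sigma=1: K=1.5, chi2=0.5."""
        p = sk.ScatteringProfile([0.01, 0.02], [2.0, 1.0], [1.0, 1.0])
        fit = sk.chi2_fit(p, [1.0, 1.0])
        assert fit.k_scale == pytest.approx(1.5)
        assert fit.chi2 == pytest.approx(0.5)
        assert fit.n_points == 2

    def test_rescaling_model_does_not_change_chi2(self):
        rng = np.random.default_rng(0)
        i_exp = rng.uniform(1, 10, 30)
        i_model = rng.uniform(1, 10, 30)
        p = sk.ScatteringProfile(np.linspace(0.01, 0.04, 30), i_exp, 0.1 * i_exp)
        a = sk.chi2_fit(p, i_model)
        b = sk.chi2_fit(p, 7.3 * i_model)
        assert b.chi2 == pytest.approx(a.chi2, rel=1e-12)
        assert b.k_scale == pytest.approx(a.k_scale / 7.3, rel=1e-12)

    def test_zero_model_rejected(self):
        p = sk.ScatteringProfile([0.01, 0.02], [2.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            sk.chi2_fit(p, [0.0, 0.0])


class TestEnantiomer:
    def test_profile_identical(self):
        rng = np.random.default_rng(5)
        m = sk.BeadModel(rng.uniform(-20, 20, (60, 3)))
        s = np.linspace(0.002, 0.08, 40)
        a = sk.debye_intensity(m, s)
        b = sk.debye_intensity(sk.enantiomer(m), s)
        assert np.abs(b / a - 1).max() < 1e-12

    def test_involution(self):
        rng = np.random.default_rng(6)
        m = sk.BeadModel(rng.uniform(-20, 20, (30, 3)))
        assert np.array_equal(sk.enantiomer(sk.enantiomer(m)).coords, m.coords)

    def test_planar_model_is_self_mirror(self):
        coords = np.column_stack([np.arange(5.0), np.arange(5.0) ** 2, np.zeros(5)])
        m = sk.BeadModel(coords)
        assert np.array_equal(sk.enantiomer(m).coords, m.coords)


class TestRestoreShape:
    def test_sphere_target_converges(self):
        model, target = small_sphere_target()
        res = sk.restore_shape(target, 80, dmax_hint=40.0, seed=3, schedule=FAST)
        assert res.fit.chi2 < 5.0
        assert res.model.radius_of_gyration() == pytest.approx(
            model.radius_of_gyration(), rel=0.10
        )
        assert res.model.bead_diameter == pytest.approx(3.8)

    def test_seeded_determinism(self):
        _, target = small_sphere_target()
        kw = dict(n_dr=40, dmax_hint=40.0, seed=9, schedule=FAST)
        a = sk.restore_shape(target, **kw)
        b = sk.restore_shape(target, **kw)
        assert np.array_equal(a.model.coords, b.model.coords)
        assert a.fit.chi2 == b.fit.chi2

    def test_best_energy_envelope_non_increasing(self):
        _, target = small_sphere_target()
        res = sk.restore_shape(target, 40, dmax_hint=40.0, seed=1, schedule=FAST)
        trace = np.array(res.energy_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_c2_symmetry_enforced_exactly(self):
        dim = sk.generate_shape(
            sk.ShapeSpec(kind="c2_dimer", n_beads=300, domain_radii=(12.0, 12.0)), seed=4
        )
        s = np.linspace(0.002, 0.03, 50)
        i = sk.debye_intensity(dim, s)
        target = sk.ScatteringProfile(s, i, 0.01 * i)
        res = sk.restore_shape(target, 60, dmax_hint=70.0, symmetry="C2", seed=5,
                               schedule=FAST)
        assert res.symmetry_used == "C2"
        assert res.model.satisfies_c2(1e-6)
        assert res.n_dr % 2 == 0

    def test_incremental_debye_consistent_with_exact(self):
        """The annealer's binned intensity must track the exact sum."""
        from saxskit.restore import _Annealer

        _, target = small_sphere_target()
        rng = np.random.default_rng(7)
        ann = _Annealer(target, 60, 40.0, "none", rng, (3.8, 5.7), 5.7, 2.0, 0.2, 6.0)
        for _ in range(200):  # scramble through some accepted moves
            moved, pos = ann.propose()
            iv, nbr = ann._move_delta(moved, pos)
            ann.commit(moved, pos, iv, nbr)
        i_inc = ann.n + 2.0 * ann.iv
        i_exact = sk.debye_intensity(sk.BeadModel(ann.coords), target.s_grid, method="exact")
        assert np.abs(i_inc / i_exact - 1).max() < 1e-3

    def test_preconditions(self):
        _, target = small_sphere_target()
        with pytest.raises(ValueError):
            sk.restore_shape(target, 5, dmax_hint=40.0)  # too few beads
        flat = target.with_(sigma=np.zeros_like(target.sigma))
        with pytest.raises(ValueError):
            sk.restore_shape(flat, 40, dmax_hint=40.0)  # needs positive errors


class TestScanDrCount:
    def test_single_count_trivial(self):
        _, target = small_sphere_target()
        best, table = sk.scan_dr_count(target, [40], replicates=1, seed=0,
                                       dmax_hint=40.0, schedule=FAST)
        assert best == 40
        assert len(table) == 1

    def test_empty_counts_rejected(self):
        _, target = small_sphere_target()
        with pytest.raises(ValueError):
            sk.scan_dr_count(target, [], replicates=1)

    def test_table_is_reproducible(self):
        _, target = small_sphere_target()
        tiny = AnnealSchedule(max_levels=4, moves_per_bead=5, patience=3)
        _, t1 = sk.scan_dr_count(target, [20, 40], replicates=2, seed=3,
                                 dmax_hint=40.0, schedule=tiny)
        _, t2 = sk.scan_dr_count(target, [20, 40], replicates=2, seed=3,
                                 dmax_hint=40.0, schedule=tiny)
        assert t1.equals(t2)
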