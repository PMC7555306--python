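import math

import numpy as np
import pytest

import saxskit as sk
from saxskit.guinier import FOUR_PI2_OVER_3, GuinierResult

RG_SPHERE = math.sqrt(3 / 5) * 30.0


def exact_guinier_profile(i0=100.0, rg=20.0, noise=0.01, n=80, s_max=0.02):
    s = np.linspace(0.002, s_max, n)
    i = i0 * np.exp(-FOUR_PI2_OVER_3 * rg**2 * s**2)
    return sk.ScatteringProfile(s, i, noise * i)


class TestGuinierFit:
    def test_exact_form_recovered_to_machine_precision(self):
        p = exact_guinier_profile()
        g = sk.guinier_fit(p)
        assert g.rg == pytest.approx(20.0, rel=1e-9)
        assert g.i0 == pytest.approx(100.0, rel=1e-9)
        assert g.n_points >= 5
        assert g.srg_max <= 1.3 + 1e-6

    def test_bead_sphere_profile(self, sphere_profile):
        g = sk.guinier_fit(sphere_profile)
        assert g.rg == pytest.approx(RG_SPHERE, rel=0.02)

    def test_aggregation_like_rise_rejected_or_flagged(self):
        s = np.linspace(0.002, 0.02, 60)
        i = 100 * np.exp(+5000.0 * s**2)  # intensity rising at low angle
        p = sk.ScatteringProfile(s, i, 0.01 * i)
        with pytest.raises(ValueError, match="no Guinier region"):
            sk.guinier_fit(p)

    def test_too_few_points(self):
        p = sk.ScatteringProfile([0.01, 0.02, 0.03], [3.0, 2.0, 1.0], [0.1] * 3)
        with pytest.raises(ValueError):
            sk.guinier_fit(p)


class TestExtrapolateDilution:
    @staticmethod
    def synthetic_results(mw=51000.0, a2=2e-7, bif=2.0, rg0=30.0, k=1.0,
                          concs=(1.0, 2.5, 5.0)):
        out = []
        for c in concs:
            i0 = k * c * mw / (1.0 + 2.0 * a2 * mw * c)
            rg = math.sqrt(rg0**2 - bif * c)
            out.append((c, GuinierResult(rg=rg, rg_err=0.01, i0=i0, i0_err=i0 * 1e-4,
                                         fit_window=(0.002, 0.01), n_points=10,
                                         r_squared=1.0)))
        return out

    def test_exact_on_law_constructed_data(self):
        """Data built directly from the dilution laws comes back exactly."""
        d = sk.extrapolate_dilution(self.synthetic_results(), k_const=1.0)
        assert d.mw_apparent == pytest.approx(51000.0, rel=1e-10)
        assert d.a2 == pytest.approx(2e-7, rel=1e-8)
        assert d.bif == pytest.approx(2.0, rel=1e-10)
        assert d.rg0 == pytest.approx(30.0, rel=1e-12)
        assert d.monodisperse

    def test_noiseless_simulated_series_roundtrip(self):
        model = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=1000, radius=30.0), seed=2)
        spec = sk.SeriesSpec(noise_level=0.0, a2_true=0.0, bif_true=0.0)
        series = sk.simulate_series(model, None, spec)["dark"]
        gs = [(p.concentration, sk.guinier_fit(p)) for p in series]
        d = sk.extrapolate_dilution(gs)
        assert d.mw_apparent == pytest.approx(51000.0, rel=0.005)
        assert abs(d.a2) < 1e-12
        assert abs(d.bif) < 1e-6

    def test_interference_parameters_recovered(self):
        model = sk.generate_shape(sk.ShapeSpec(kind="sphere", n_beads=1000, radius=30.0), seed=2)
        spec = sk.SeriesSpec(noise_level=0.0)  # a2 = 2e-7, bif = 2.0
        series = sk.simulate_series(model, None, spec)["dark"]
        d = sk.extrapolate_dilution([(p.concentration, sk.guinier_fit(p)) for p in series])
        assert d.bif == pytest.approx(2.0, rel=1e-6)
        assert d.a2 == pytest.approx(2e-7, rel=0.02)

    def test_needs_three_distinct_concentrations(self):
        res = self.synthetic_results(concs=(1.0, 2.0))
        with pytest.raises(ValueError):
            sk.extrapolate_dilution(res)
        res = self.synthetic_results(concs=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            sk.extrapolate_dilution(res)

    def test_nonlinear_series_flagged_polydisperse(self):
        res = self.synthetic_results()
        # corrupt one Rg badly but claim tiny errors -> r^2 collapses
        c, g = res[1]
        res[1] = (c, GuinierResult(rg=g.rg * 1.5, rg_err=0.01, i0=g.i0, i0_err=g.i0 * 1e-4,
                                   fit_window=g.fit_window, n_points=10, r_squared=1.0))
        d = sk.extrapolate_dilution(res)
        assert not d.monodisperse
        assert d.reasons


class TestEstimateMw:
    def test_identity_and_scaling(self):
        assert sk.estimate_mw(1.0, (14300.0, 1.0)) == pytest.approx(14300.0)
        assert sk.estimate_mw(2.0, (14300.0, 1.0)) == pytest.approx(28600.0)

    def test_doubles_for_dimer_forward_scattering(self):
        mono = sk.estimate_mw(0.37, (14300.0, 1.0))
        dimer = sk.estimate_mw(0.74, (14300.0, 1.0))
        assert dimer == pytest.approx(2 * mono)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sk.estimate_mw(0.0, (14300.0, 1.0))
        with pytest.raises(ValueError):
            sk.estimate_mw(1.0, (14300.0, 0.0))


class TestDifferenceProfile:
    def test_identical_curves_give_zero(self):
        p = exact_guinier_profile()
        d = sk.difference_profile(p, p)
        assert np.allclose(d.profile.intensity, 0.0)
        assert d.max_rel_diff == 0.0

    def test_six_percent_scale_difference(self):
        a = exact_guinier_profile()
        b = a.with_(intensity=0.94 * a.intensity)
        d = sk.difference_profile(a, b, normalize="none")
        assert d.max_rel_diff == pytest.approx(0.06, rel=1e-9)

    def test_sigma_propagates_in_quadrature(self):
        a = exact_guinier_profile(noise=0.01)
        d = sk.difference_profile(a, a)
        assert np.allclose(d.profile.sigma, math.sqrt(2) * a.sigma)

    def test_disjoint_ranges_error(self):
        a = sk.ScatteringProfile([0.01, 0.02], [2.0, 1.0], [0.1, 0.1])
        b = sk.ScatteringProfile([0.05, 0.06], [2.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            sk.difference_profile(a, b, interpolate=True)

    def test_hinge_bend_signature_is_low_angle(self, tandem_model, bent_tandem_model):
        """A rigid hinge bend changes mainly the smallest angles."""
        s = sk.default_s_grid()
        pa = sk.debye_profile(tandem_model, s)
        pb = sk.debye_profile(bent_tandem_model, s)
        low = sk.difference_profile(pa, pb, normalize="i0", s_window=(0.0, 0.012))
        high = sk.difference_profile(pa, pb, normalize="i0", s_window=(0.03, 0.08))
        assert low.max_rel_diff > 0.01
        assert low.max_rel_diff_s < 0.012
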