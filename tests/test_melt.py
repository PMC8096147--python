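"""Two-state melting thermodynamics: forward model, fits, aggregation."""

import numpy as np
import pytest
from scipy import optimize, stats

from deazarna import synth
from deazarna.constants import R_CAL, T_REF, celsius_to_kelvin
from deazarna.melt import (
    MeltingCurve, NoTransitionError, ThermoParams, TmConcentrationModel,
    TwoStateMeltModel, aggregate_replicates, compare_to_reference, delta_g,
    fit_baselines, read_melting_csv, theta_two_state, tm_concentration_fit,
    tm_first_derivative, tm_from_params, van_t_hoff_fit,
)
from deazarna.seqmod import Molecularity

HAIRPIN = Molecularity.UNIMOLECULAR_HAIRPIN
SELF = Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY
NONSELF = Molecularity.BIMOLECULAR_NONSELF

FLAT = synth.BaselinePair(0.0, 1.0, 0.0, 1.2)


def make_curve(dh, ds, molecularity, c_t=1e-5, baselines=FLAT,
               sigma=0.0, seed=None, t_start=20.0, t_stop=90.0):
    sc = synth.MeltScenario(dh=dh, ds=ds, molecularity=molecularity,
                            concentrations=[c_t], baselines=baselines,
                            t_start=t_start, t_stop=t_stop,
                            noise=synth.NoiseSpec(sigma, seed))
    return synth.gen_melting_curves(sc)[0]


# ---------------------------------------------------------------------------
# derivative Tm
# ---------------------------------------------------------------------------

class TestDerivativeTm:
    def test_symmetric_sigmoid_centre(self):
        # logistic centred at 330.00 K with flat baselines: symmetry puts
        # the derivative maximum exactly at the centre, 56.85 degC
        t_c = np.arange(20.0, 90.01, 0.5)
        theta = 1.0 / (1.0 + np.exp((celsius_to_kelvin(t_c) - 330.0) / 2.0))
        curve = MeltingCurve(t_c, 1.0 - theta)
        assert tm_first_derivative(curve) == pytest.approx(56.85, abs=0.05)

    def test_hairpin_against_dense_grid_oracle(self):
        # oracle: closed-form theta on a millikelvin grid, maximum of dA/dT.
        # The derivative maximum of a two-state curve sits slightly below
        # Tm = dH/dS (the 1/T^2 factor in dtheta/dT skews it), so the
        # derivative Tm is compared to the oracle, and to the closed-form
        # Tm only within the usual 0.3 degC reading accuracy.
        dh, ds = -52.8, -153.0
        t_dense = np.arange(celsius_to_kelvin(20.0), celsius_to_kelvin(90.0),
                            1e-3)
        theta = theta_two_state(t_dense, dh, ds, HAIRPIN)
        a = 1.0 - theta
        oracle_tm = t_dense[np.argmax(np.gradient(a, t_dense))] - 273.15
        assert oracle_tm == pytest.approx(1000.0 * dh / ds - 273.15, abs=0.3)

        curve = make_curve(dh, ds, HAIRPIN)
        got = tm_first_derivative(curve)
        assert got == pytest.approx(oracle_tm, abs=0.15)
        assert got == pytest.approx(1000.0 * dh / ds - 273.15, abs=0.3)

    def test_sloping_baselines_theta_derivative_within_300mK(self):
        # with sloping baselines the derivative is taken on the
        # baseline-corrected folded fraction instead of raw absorbance
        dh, ds = -52.8, -153.0
        flat_tm = tm_first_derivative(make_curve(dh, ds, HAIRPIN))
        truth = synth.BaselinePair(0.0005, 1.0, -0.0005, 1.2)
        sloped = make_curve(dh, ds, HAIRPIN, baselines=truth)
        t = sloped.temperature
        gap = truth.unfolded(t) - truth.folded(t)
        theta = (truth.unfolded(t) - sloped.absorbance) / gap
        got = tm_first_derivative(sloped, theta=theta)
        assert got == pytest.approx(flat_tm, abs=0.3)

    def test_featureless_curve_raises(self):
        t_c = np.arange(20.0, 90.01, 0.5)
        curve = MeltingCurve(t_c, 1.0 + 0.001 * t_c)
        with pytest.raises(NoTransitionError):
            tm_first_derivative(curve)


# ---------------------------------------------------------------------------
# baselines and theta
# ---------------------------------------------------------------------------

class TestBaselines:
    def test_flat_baselines_recover_theta(self):
        dh, ds = -60.0, -182.9   # Tm ~ 328 K, transition well inside range
        curve = make_curve(dh, ds, HAIRPIN, baselines=synth.BaselinePair(
            0.0, 0.0, 0.0, 1.0))
        theta_true = theta_two_state(curve.temperature_k, dh, ds, HAIRPIN)
        _pair, theta = fit_baselines(curve)
        assert np.max(np.abs(theta - theta_true)) < 0.02

    def test_theta_is_half_at_tm(self):
        dh, ds = -60.0, -182.9
        curve = make_curve(dh, ds, HAIRPIN)
        _pair, theta = fit_baselines(curve)
        tm_c = 1000.0 * dh / ds - 273.15
        assert np.interp(tm_c, curve.temperature, theta) == \
            pytest.approx(0.5, abs=0.02)

    def test_recovers_generator_baselines(self):
        truth = synth.BaselinePair(0.0003, 1.0, 0.0005, 1.2)
        curve = make_curve(-60.0, -182.9, HAIRPIN, baselines=truth)
        pair, _theta = fit_baselines(curve)
        assert pair.folded_intercept == pytest.approx(1.0, abs=5e-3)
        assert pair.unfolded_intercept == pytest.approx(1.2, abs=5e-3)
        assert pair.folded_slope == pytest.approx(0.0003, abs=1e-4)
        assert pair.unfolded_slope == pytest.approx(0.0005, abs=1e-4)

    def test_degenerate_baselines_error(self):
        t_c = np.arange(20.0, 90.01, 0.5)
        curve = MeltingCurve(t_c, np.full(t_c.size, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_baselines(curve)


# ---------------------------------------------------------------------------
# van't Hoff single-curve fit
# ---------------------------------------------------------------------------

class TestVantHoffFit:
    @pytest.mark.parametrize("dh, ds, mol, c_t", [
        (-52.8, -153.0, HAIRPIN, np.nan),
        (-64.6, -172.0, SELF, 1e-5),
        (-79.7, -212.0, NONSELF, 1e-5),
    ])
    def test_noise_free_self_inversion(self, dh, ds, mol, c_t):
        params = van_t_hoff_fit(make_curve(dh, ds, mol, c_t=c_t))
        assert params.dh == pytest.approx(dh, rel=1e-4)
        assert params.ds == pytest.approx(ds, rel=1e-4)
        # reported dG must equal dH - T dS / 1000 for the fitted pair
        assert params.dg298 == pytest.approx(
            params.dh - T_REF * params.ds / 1000.0, abs=1e-9)

    def test_unimolecular_tm_closed_form(self):
        params = van_t_hoff_fit(make_curve(-52.8, -153.0, HAIRPIN))
        assert celsius_to_kelvin(params.tm) == \
            pytest.approx(1000.0 * params.dh / params.ds, abs=1e-3)

    def test_self_complementary_tm_matches_root_finding_oracle(self):
        # oracle: solve theta(T) = 1/2 on the closed-form curve directly
        dh, ds, c_t = -64.6, -172.0, 1e-5
        tm_oracle = optimize.brentq(
            lambda t: theta_two_state(t, dh, ds, SELF, c_t) - 0.5,
            280.0, 380.0)
        tm_closed = tm_from_params(dh, ds, SELF, c_t)
        assert tm_oracle == pytest.approx(tm_closed, abs=1e-6)
        params = van_t_hoff_fit(make_curve(dh, ds, SELF, c_t=c_t))
        assert celsius_to_kelvin(params.tm) == \
            pytest.approx(tm_oracle, abs=1e-3)

    def test_unimolecular_tm_concentration_invariant(self):
        tms = [van_t_hoff_fit(make_curve(-52.8, -153.0, HAIRPIN, c_t=c)).tm
               for c in (1e-6, 1e-5, 1e-4)]
        assert np.ptp(tms) < 0.05

    def test_recovery_under_noise(self):
        # transition-amplitude-relative noise, a few seeds per molecularity
        truths = {HAIRPIN: (-52.8, -153.0), SELF: (-64.6, -172.0),
                  NONSELF: (-79.7, -212.0)}
        dh_errs, tm_errs = [], []
        for mol, (dh, ds) in truths.items():
            for seed in range(6):
                c_t = 1e-5
                curve = make_curve(dh, ds, mol, c_t=c_t, sigma=6e-4,
                                   seed=seed)
                p = van_t_hoff_fit(curve)
                dh_errs.append(abs((p.dh - dh) / dh))
                tm_true = tm_from_params(dh, ds, mol, c_t) - 273.15
                tm_errs.append(abs(p.tm - tm_true))
        assert np.median(dh_errs) < 0.05
        assert np.median(tm_errs) < 0.3

    def test_summary_mentions_key_quantities(self):
        res = TwoStateMeltModel(make_curve(-52.8, -153.0, HAIRPIN)).fit()
        text = res.summary()
        assert "Tm" in text and "dH" in text and "kcal/mol" in text


def test_sharpness_increases_with_enthalpy_at_fixed_tm():
    # steeper transitions for larger |dH|: max |dtheta/dT| strictly grows
    tm_k = 330.0
    t = np.arange(280.0, 380.0, 0.01)
    slopes = []
    for dh in (-40.0, -60.0, -80.0, -120.0):
        ds = 1000.0 * dh / tm_k
        theta = theta_two_state(t, dh, ds, HAIRPIN)
        slopes.append(np.max(np.abs(np.gradient(theta, t))))
    assert np.all(np.diff(slopes) > 0)


# ---------------------------------------------------------------------------
# Tm versus concentration
# ---------------------------------------------------------------------------

class TestTmConcentration:
    CONCS = np.array([1e-6, 3e-6, 1e-5, 3e-5, 1e-4])

    def test_exact_recovery_nonself(self):
        # forward closed form 1/Tm = (R/1000 dH) ln(c/4) + dS/(1000 dH)
        dh, ds = -79.7, -212.0
        tm = 1000.0 * dh / (R_CAL * np.log(self.CONCS / 4.0) + ds)
        params = tm_concentration_fit(list(zip(tm, self.CONCS)), NONSELF)
        assert params.dh == pytest.approx(dh, rel=1e-9)
        assert params.ds == pytest.approx(ds, rel=1e-9)

    def test_exact_recovery_self_complementary(self):
        dh, ds = -64.6, -172.0
        tm = 1000.0 * dh / (R_CAL * np.log(self.CONCS) + ds)
        params = tm_concentration_fit(list(zip(tm, self.CONCS)), SELF)
        assert params.dh == pytest.approx(dh, rel=1e-9)
        assert params.ds == pytest.approx(ds, rel=1e-9)

    def test_agrees_with_single_curve_fits(self):
        # the two independent estimation routes must agree on clean data
        dh, ds = -64.6, -172.0
        tms, concs = [], []
        for c in self.CONCS:
            p = van_t_hoff_fit(make_curve(dh, ds, SELF, c_t=c))
            tms.append(celsius_to_kelvin(p.tm))
            concs.append(c)
        params = tm_concentration_fit(list(zip(tms, concs)), SELF)
        assert params.dh == pytest.approx(dh, rel=1e-3)

    def test_unimolecular_rejected(self):
        with pytest.raises(ValueError, match="concentration-independent"):
            TmConcentrationModel([330, 331, 332], [1e-6, 1e-5, 1e-4], HAIRPIN)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            TmConcentrationModel([330, 331], [1e-6, 1e-5], SELF)

    def test_rank_deficient(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            TmConcentrationModel([330.0, 330.0, 330.0],
                                 [1e-5, 1e-5, 1e-5], SELF).fit()

    def test_positive_slope_flagged(self):
        tm = np.array([330.0, 331.0, 332.0, 333.0])   # Tm falls with c
        c = np.array([1e-4, 1e-5, 1e-6, 1e-7])
        with pytest.warns(UserWarning, match="non-negative slope"):
            res = TmConcentrationModel(tm, c, SELF).fit()
        assert "non_two_state_positive_slope" in res.params.flags


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

class TestDeltaG:
    @pytest.mark.parametrize("dh, ds, expected", [
        (-79.7, -212.0, -16.5),   # published duplex values
        (-76.6, -203.0, -16.1),
        (-51.5, -151.0, -6.5),
        (-70.6, -192.0, -13.4),
    ])
    def test_reported_rows(self, dh, ds, expected):
        assert round(delta_g(dh, ds), 1) == expected

    def test_zero_entropy(self):
        for t in (250.0, 298.15, 400.0):
            assert delta_g(-50.0, 0.0, t=t) == -50.0

    def test_accepts_thermo_params(self):
        p = ThermoParams(dh=-79.7, ds=-212.0, tm=66.7)
        assert delta_g(p) == pytest.approx(-16.49, abs=0.01)


class TestCompare:
    def test_published_dtm_values(self):
        ref = ThermoParams(dh=-64.6, ds=-172.0, tm=58.3)
        mod = ThermoParams(dh=-74.7, ds=-213.0, tm=44.8)
        dtm, ddg = compare_to_reference(mod, ref)
        assert dtm == pytest.approx(-13.5)
        assert ddg == pytest.approx(mod.dg298 - ref.dg298)

    def test_identity(self):
        p = ThermoParams(dh=-79.7, ds=-212.0, tm=66.7)
        assert compare_to_reference(p, p) == (0.0, 0.0)

    def test_small_shift(self):
        ref = ThermoParams(dh=-79.7, ds=-212.0, tm=66.7)
        mod = ThermoParams(dh=-74.8, ds=-199.0, tm=62.8)
        assert compare_to_reference(mod, ref)[0] == pytest.approx(-3.9)


class TestAggregate:
    def _fit(self, dh, ds=-212.0, tm=66.7):
        return ThermoParams(dh=dh, ds=ds, tm=tm)

    def test_identical_fits_zero_width(self):
        agg = aggregate_replicates([self._fit(-79.7)] * 3)
        assert agg.dh == pytest.approx(-79.7)
        assert agg.dh_err == 0.0
        assert agg.error_kind == "ci95"
        assert agg.n == 3

    def test_t_interval_against_statistics_oracle(self):
        fits = [self._fit(v) for v in (-79.0, -80.0, -81.0)]
        agg = aggregate_replicates(fits)
        sd = np.std([-79.0, -80.0, -81.0], ddof=1)
        expected = stats.t.ppf(0.975, 2) * sd / np.sqrt(3)
        assert agg.dh == pytest.approx(-80.0)
        assert agg.dh_err == pytest.approx(expected)

    def test_sd_option(self):
        fits = [self._fit(v) for v in (-79.0, -80.0, -81.0)]
        agg = aggregate_replicates(fits, ci="sd")
        assert agg.dh_err == pytest.approx(1.0)
        assert agg.error_kind == "sd"

    def test_single_fit_warns(self):
        with pytest.warns(UserWarning, match="single replicate"):
            agg = aggregate_replicates([self._fit(-79.7)])
        assert agg.n == 1


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_read_melting_csv_long_format(tmp_path):
    import pandas as pd

    curves_in = synth.gen_melting_curves(synth.MeltScenario(
        dh=-64.6, ds=-172.0, molecularity=SELF,
        concentrations=[1e-6, 1e-5]))
    frames = []
    for i, c in enumerate(curves_in):
        frames.append(pd.DataFrame({
            "temperature_C": c.temperature, "absorbance": c.absorbance,
            "replicate": f"r{i}", "concentration_M": c.c_t,
        }))
    path = tmp_path / "melt.csv"
    pd.concat(frames).to_csv(path, index=False)
    curves_out = read_melting_csv(path, SELF)
    assert len(curves_out) == 2
    np.testing.assert_allclose(curves_out[0].absorbance,
                               curves_in[0].absorbance)
    assert curves_out[1].c_t == pytest.approx(1e-5)
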