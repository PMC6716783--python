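"""Ratiometric kinetics, AUC, logistic dose-response, binding fits and
the delta-delta logEC50 bias ledger."""

import numpy as np
import pandas as pd
import pytest

from nanodyn.pharmacology import (
    KineticTrace,
    auc_response,
    bias_estimate,
    fit_association_kinetics,
    fit_logistic,
    fit_saturation_binding,
    membrane_profile_series,
    normalize_to_baseline,
    ratiometric_trace,
)
from nanodyn.synthetic import (
    association_response,
    logistic_response,
    simulate_binding_traces,
    simulate_dose_response,
)


def make_trace(times, num, den, blanks=None):
    return KineticTrace(
        times=times,
        channels={665.0: np.asarray(num, float), 616.0: np.asarray(den, float)},
        blanks=blanks or {},
        baseline_window=(times[0], times[len(times) // 3]),
    )


class TestRatiometricTrace:
    def test_equal_channels_flat_one(self):
        t = np.arange(10.0)
        trace = make_trace(t, np.full(10, 7.0), np.full(10, 7.0))
        np.testing.assert_allclose(ratiometric_trace(trace, 665, 616), 1.0)

    def test_blank_subtraction(self):
        t = np.arange(5.0)
        trace = make_trace(t, np.full(5, 10.0), np.full(5, 6.0),
                           blanks={665.0: 4.0, 616.0: 3.0})
        np.testing.assert_allclose(ratiometric_trace(trace, 665, 616), 2.0)

    def test_zero_denominator_raises_listing_times(self):
        t = np.arange(5.0)
        trace = make_trace(t, np.full(5, 10.0), np.full(5, 3.0),
                           blanks={616.0: 3.0})
        with pytest.raises(ZeroDivisionError):
            ratiometric_trace(trace, 665, 616)

    def test_missing_channel(self):
        t = np.arange(5.0)
        trace = make_trace(t, np.ones(5), np.ones(5))
        with pytest.raises(KeyError):
            ratiometric_trace(trace, 520, 616)


class TestBaselineAndAUC:
    def test_constant_series_normalizes_to_one(self):
        t = np.arange(20.0)
        out, base = normalize_to_baseline(np.full(20, 5.0), t, (0.0, 5.0))
        np.testing.assert_allclose(out, 1.0)
        assert base == 5.0

    def test_step_response_plateau(self):
        t = np.arange(30.0)
        y = np.where(t < 10, 2.0, 6.0)
        out, _ = normalize_to_baseline(y, t, (0.0, 9.0))
        assert out[-1] == pytest.approx(3.0)

    def test_nonpositive_baseline_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            normalize_to_baseline(np.zeros(10), t, (0.0, 5.0))

    def test_flat_normalized_trace_has_zero_auc(self):
        t = np.arange(10.0)
        assert auc_response(np.ones(10), t) == 0.0

    def test_unit_step_auc_equals_duration(self):
        t = np.arange(0.0, 101.0)
        y = np.ones_like(t)
        y[t >= 50] = 2.0
        # trapezoid ramp at the step contributes half an interval
        assert auc_response(y, t) == pytest.approx(50.5)

    def test_auc_linearity(self, rng):
        t = np.sort(rng.uniform(0, 60, 40))
        s = 1.0 + rng.normal(0, 0.5, 40)
        a = 3.7
        assert auc_response(a * (s - 1.0) + 1.0, t) == pytest.approx(
            a * auc_response(s, t)
        )

    def test_raw_mode_matches_fine_grid_oracle(self):
        t = np.linspace(0, 10, 21)
        y = np.sin(t / 3.0) + 2.0
        coarse = auc_response(y, t, mode="raw")
        tf = np.linspace(0, 10, 20001)
        fine = np.trapezoid(np.sin(tf / 3.0) + 2.0, tf)
        assert coarse == pytest.approx(fine, rel=5e-3)


class TestLogisticFit:
    DOSES = np.logspace(-12, -6, 8)

    def test_exact_recovery_noise_free(self):
        y = logistic_response(self.DOSES, 0.0, 100.0, -9.0, 1.0)
        fit = fit_logistic(self.DOSES, y)
        assert fit.converged
        assert fit.log_ec50 == pytest.approx(-9.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_three_parameter_mode_fixes_hill(self):
        y = logistic_response(self.DOSES, 2.0, 80.0, -8.5, 1.0)
        fit = fit_logistic(self.DOSES, y, n_params=3)
        assert fit.hill == 1.0
        assert fit.log_ec50 == pytest.approx(-8.5, abs=1e-6)

    def test_midpoint_identity(self):
        y = logistic_response(self.DOSES, 10.0, 90.0, -9.0, 1.3)
        fit = fit_logistic(self.DOSES, y)
        mid = logistic_response(np.array([fit.ec50_m]), fit.bottom, fit.top,
                                fit.log_ec50, fit.hill)[0]
        assert mid == pytest.approx((fit.top + fit.bottom) / 2, rel=1e-9)

    def test_vehicle_anchors_bottom(self):
        doses = np.concatenate([[0.0], self.DOSES])
        y = logistic_response(doses, 5.0, 95.0, -9.0, 1.0)
        fit = fit_logistic(doses, y)
        assert fit.bottom == pytest.approx(5.0, abs=1e-6)

    def test_dose_unit_rescaling_shifts_log_ec50_only(self):
        y = logistic_response(self.DOSES, 0.0, 100.0, -9.0, 1.0)
        fit_m = fit_logistic(self.DOSES, y)
        fit_nm = fit_logistic(self.DOSES * 1e9, y)
        assert fit_nm.log_ec50 == pytest.approx(fit_m.log_ec50 + 9.0, abs=1e-6)
        assert fit_nm.top == pytest.approx(fit_m.top, rel=1e-9)
        assert fit_nm.hill == pytest.approx(fit_m.hill, rel=1e-6)

    def test_simulation_study_bias_and_se(self):
        """200-seed noisy simulation: logEC50 recovered with small bias
        and roughly nominal CI coverage."""
        from scipy import stats

        true_lec = -9.0
        # Wald interval for nonlinear LS uses the t quantile at the
        # residual degrees of freedom (8 doses - 4 parameters)
        t_crit = stats.t.ppf(0.975, df=self.DOSES.size - 4)
        estimates, covered = [], []
        for seed in range(200):
            df = simulate_dose_response(self.DOSES, bottom=0, top=100,
                                        log_ec50=true_lec, hill=1.0,
                                        noise_sd=2.0, seed=seed)
            fit = fit_logistic(df["dose_M"].to_numpy(), df["response"].to_numpy())
            if not fit.converged:
                continue
            estimates.append(fit.log_ec50)
            se = fit.se.get("log_ec50", np.nan)
            covered.append(abs(fit.log_ec50 - true_lec) <= t_crit * se)
        assert abs(np.mean(estimates) - true_lec) < 0.05
        assert 0.90 <= np.mean(covered) <= 0.99

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.array([1e-9, 1e-8, 1e-7]), np.array([1.0, 2.0, 3.0]))


class TestBiasEstimate:
    @staticmethod
    def table(shift=0.0, agonist="A2", pathway="lyn"):
        rows = []
        base = {"A1": -9.0, "A2": -8.0, "A3": -8.5}
        for exp in (1, 2, 3):
            for ag, lec in base.items():
                for pw in ("nes", "lyn"):
                    val = lec + (shift if (ag == agonist and pw == pathway) else 0.0)
                    rows.append({"agonist": ag, "pathway": pw,
                                 "experiment": exp, "log_ec50": val})
        return pd.DataFrame(rows)

    def test_identical_potencies_give_zero_bias(self):
        df = self.table()
        est = bias_estimate(df, "A1", "nes", "lyn")
        np.testing.assert_allclose(est.per_experiment["delta_delta_log_ec50"], 0.0)

    def test_reference_agonist_identically_zero(self):
        est = bias_estimate(self.table(shift=0.7), "A1", "nes", "lyn")
        ref = est.per_experiment.query("agonist == 'A1'")
        np.testing.assert_allclose(ref["delta_delta_log_ec50"], 0.0)

    def test_injected_pathway_shift_recovered(self):
        """A +0.5 log potency shift for one agonist in the test pathway
        appears as delta-delta = +0.5 (less potent in test pathway =>
        bias toward the reference pathway is negative... sign follows the
        reference-minus-test convention)."""
        est = bias_estimate(self.table(shift=0.5, agonist="A2", pathway="lyn"),
                            "A1", "nes", "lyn")
        a2 = est.summary.set_index("agonist").loc["A2", "delta_delta_log_ec50"]
        # shift of +0.5 in logEC50(lyn) makes A2 *less* potent in lyn:
        # delta(lyn) = lec(A1) - (lec(A2)+0.5) decreases by 0.5, so
        # delta_delta = delta(nes) - delta(lyn) increases by 0.5
        assert a2 == pytest.approx(0.5, abs=1e-12)

    def test_pathway_swap_flips_sign(self):
        df = self.table(shift=0.5, agonist="A2", pathway="lyn")
        a = bias_estimate(df, "A1", "nes", "lyn")
        b = bias_estimate(df, "A1", "lyn", "nes")
        sa = a.summary.set_index("agonist")["delta_delta_log_ec50"]
        sb = b.summary.set_index("agonist")["delta_delta_log_ec50"]
        np.testing.assert_allclose(sa.to_numpy(), -sb.to_numpy(), atol=1e-12)

    def test_missing_cell_named(self):
        df = self.table().drop(index=[3])
        with pytest.raises(ValueError, match="missing cell"):
            bias_estimate(df, "A1", "nes", "lyn")


class TestSaturationBinding:
    def test_exact_recovery(self):
        conc = np.logspace(-10, -7, 8)
        y = 100.0 * conc / (1e-8 + conc)
        fit = fit_saturation_binding(conc, y)
        assert fit.kd == pytest.approx(1e-8, rel=1e-6)
        assert fit.bmax == pytest.approx(100.0, rel=1e-6)

    def test_half_occupancy_at_kd(self):
        conc = np.logspace(-10, -7, 8)
        y = 80.0 * conc / (5e-9 + conc)
        fit = fit_saturation_binding(conc, y)
        occ = fit.bmax * fit.kd / (fit.kd + fit.kd)
        assert occ == pytest.approx(fit.bmax / 2)

    def test_flat_signal_flagged(self):
        fit = fit_saturation_binding(np.logspace(-10, -7, 5), np.full(5, 3.0))
        assert not fit.converged

    def test_noisy_recovery(self, rng):
        conc = np.logspace(-10, -6.5, 10)
        kds = []
        for seed in range(100):
            local = np.random.default_rng(seed)
            y = 100.0 * conc / (1e-8 + conc) + local.normal(0, 2.0, conc.size)
            fit = fit_saturation_binding(conc, y)
            if fit.converged:
                kds.append(fit.kd)
        gm = np.exp(np.mean(np.log(kds)))
        assert abs(gm - 1e-8) / 1e-8 < 0.15


class TestAssociationKinetics:
    TIMES = np.linspace(0.0, 3600.0, 60)

    def test_exact_recovery_and_kd_identity(self):
        df = simulate_binding_traces(self.TIMES, np.array([1e-9, 1e-8]),
                                     kon=1e6, koff=1e-3, bmax=100.0, noise_sd=0)
        fit = fit_association_kinetics(df)
        assert fit.kon == pytest.approx(1e6, rel=1e-5)
        assert fit.koff == pytest.approx(1e-3, rel=1e-5)
        assert fit.bmax == pytest.approx(100.0, rel=1e-5)
        assert fit.kd == pytest.approx(fit.koff / fit.kon, rel=1e-12)
        assert fit.kd == pytest.approx(1e-9, rel=1e-4)

    def test_observed_rate_affine_in_concentration(self):
        """k_obs = kon*L + koff: single-trace exponential rates measured
        from noise-free model traces are affine in L with slope kon and
        intercept koff."""
        from scipy.optimize import curve_fit

        kon, koff = 5e5, 2e-3
        concs = np.array([1e-9, 5e-9, 2e-8])
        k_obs = []
        for L in concs:
            y = association_response(self.TIMES, L, kon, koff, 80.0)

            def mono(t, plateau, k):
                return plateau * (1 - np.exp(-k * t))

            (plateau, k), _ = curve_fit(mono, self.TIMES, y, p0=[y[-1], 1e-3])
            k_obs.append(k)
        slope, intercept = np.polyfit(concs, k_obs, 1)
        assert slope == pytest.approx(kon, rel=1e-4)
        assert intercept == pytest.approx(koff, rel=1e-3)

    def test_single_concentration_rejected(self):
        df = simulate_binding_traces(self.TIMES, np.array([1e-9]), noise_sd=0)
        with pytest.raises(ValueError):
            fit_association_kinetics(df)

    def test_noisy_kd_recovery(self):
        """100-seed study: geometric-mean Kd within 15% of truth."""
        kds = []
        for seed in range(100):
            df = simulate_binding_traces(self.TIMES, np.array([1e-9, 1e-8]),
                                         kon=1e6, koff=1e-3, bmax=100.0,
                                         noise_sd=1.5, seed=seed)
            fit = fit_association_kinetics(df)
            if fit.converged and np.isfinite(fit.kd):
                kds.append(fit.kd)
        gm = np.exp(np.mean(np.log(kds)))
        assert abs(gm - 1e-9) / 1e-9 < 0.15


class TestMembraneProfiles:
    def test_constant_profiles_flat(self):
        times = np.arange(5.0)
        profiles = [[np.array([1.0, 4.0, 2.0])] * 3 for _ in times]
        series, auc = membrane_profile_series(profiles, times)
        np.testing.assert_allclose(series, 1.0)
        assert auc == 0.0

    def test_peak_halving_steps_to_half(self):
        times = np.arange(4.0)
        hi = [np.array([0.0, 8.0, 0.0])]
        lo = [np.array([0.0, 4.0, 0.0])]
        series, _ = membrane_profile_series([hi, hi, lo, lo], times)
        np.testing.assert_allclose(series, [1.0, 1.0, 0.5, 0.5])

    def test_decaying_peaks_auc_matches_integral(self):
        times = np.linspace(0.0, 10.0, 101)
        k = 0.3
        profiles = [[np.array([0.0, np.exp(-k * t), 0.0])] for t in times]
        _, auc = membrane_profile_series(profiles, times)
        exact = (1 - np.exp(-k * 10)) / k - 10.0
        assert auc == pytest.approx(exact, abs=1e-3)

    def test_zero_time_zero_signal_rejected(self):
        times = np.arange(3.0)
        profiles = [[np.zeros(3)], [np.ones(3)], [np.ones(3)]]
        with pytest.raises(ValueError):
            membrane_profile_series(profiles, times)
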