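"""Tests of the force-pCa and twitch protocols and metric extraction."""

import numpy as np
import pandas as pd
import pytest

from thinfil import (
    CaTransient,
    fit_hill,
    make_ca_transient,
    run_pca_sweep,
    simulate_ensemble,
    simulate_twitch,
    twitch_metrics,
)
from thinfil.protocols import HillFitError, solve_rise_tau
from thinfil.synthetic import SyntheticIvmaSpec, gen_ivma_points


def hill_points(f_max=1.0, pca50=6.0, n_h=3.0, pca=None):
    if pca is None:
        pca = np.linspace(7.0, 5.0, 9)
    ca = 10.0 ** (6.0 - pca)
    ca50 = 10.0 ** (6.0 - pca50)
    y = f_max * ca**n_h / (ca**n_h + ca50**n_h)
    return pd.DataFrame({"pca": pca, "response": y})


class TestHillFit:
    def test_noiseless_parameters_recovered_exactly(self):
        fit = fit_hill(hill_points(f_max=1.0, pca50=6.0, n_h=3.0))
        assert fit.f_max == pytest.approx(1.0, abs=1e-6)
        assert fit.pca50 == pytest.approx(6.0, abs=1e-6)
        assert fit.n_h == pytest.approx(3.0, abs=1e-6)
        assert fit.residual_sse < 1e-12

    def test_predict_reproduces_inputs(self):
        pts = hill_points(f_max=0.8, pca50=5.7, n_h=4.0)
        fit = fit_hill(pts)
        np.testing.assert_allclose(fit.predict(pts["pca"]), pts["response"], atol=1e-9)

    def test_all_zero_responses_raise(self):
        pts = hill_points()
        pts["response"] = 0.0
        with pytest.raises(HillFitError):
            fit_hill(pts)

    def test_flat_nonzero_responses_raise(self):
        pts = hill_points()
        pts["response"] = 0.5
        with pytest.raises(HillFitError):
            fit_hill(pts)

    def test_too_few_points_raise(self):
        with pytest.raises(HillFitError):
            fit_hill(hill_points(pca=np.array([6.5, 6.0, 5.5])))

    def test_noisy_recovery_median_error_small(self):
        # sigma = 0.02 on 10-point curves: the pCa50 estimate stays
        # within 0.05 units for the median replicate
        errs = []
        for rep in range(100):
            pts = gen_ivma_points(
                SyntheticIvmaSpec(
                    v_max=1.0, pca50=6.0, n_h=3.0, noise_sd=0.02,
                    pca_points=tuple(np.linspace(7.0, 5.0, 10)), seed=rep,
                )
            )
            errs.append(abs(fit_hill(pts).pca50 - 6.0))
        assert np.median(errs) < 0.05


class TestCaTransient:
    def test_defaults_start_at_diastolic_and_peak_at_one_micromolar(self):
        ca = make_ca_transient(CaTransient())
        assert ca(0.0) == pytest.approx(0.1, abs=1e-12)
        assert ca(-0.3) == pytest.approx(0.1, abs=1e-12)
        t = np.linspace(0, 1.0, 20001)
        vals = np.array([ca(x) for x in t])
        assert vals.max() == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(vals)] == pytest.approx(0.05, abs=1e-3)

    def test_slow_decay_limit_is_nondecreasing(self):
        spec = CaTransient(decay_tau=1e6, duration=0.5, time_to_peak=0.05)
        with pytest.warns(UserWarning):
            ca = make_ca_transient(spec)
        t = np.linspace(0, 0.5, 2001)
        vals = np.array([ca(x) for x in t])
        assert np.all(np.diff(vals) >= -1e-9)

    def test_peak_not_above_diastolic_rejected(self):
        with pytest.raises(ValueError):
            CaTransient(diastolic=1.0, peak=0.5)

    def test_rise_tau_solver_places_peak(self):
        tau_r = solve_rise_tau(0.05, 0.15)
        t = np.linspace(1e-6, 1.0, 200001)
        s = np.exp(-t / 0.15) - np.exp(-t / tau_r)
        assert t[np.argmax(s)] == pytest.approx(0.05, abs=1e-4)


class TestPcaSweep:
    def test_one_row_per_grid_point(self, set1):
        grid = [6.5, 6.0, 5.5]
        sweep = run_pca_sweep(
            set1.with_(n_units=4), grid, n_traj=2, seed=1,
            duration=1.0, window=0.5,
        )
        assert list(sweep["pca"]) == grid
        assert set(sweep.columns) >= {"pca", "force", "force_se", "drift_flag"}

    def test_activation_beyond_monte_carlo_error(self, set1):
        sweep = run_pca_sweep(
            set1, [8.0, 5.0], n_traj=6, seed=2, duration=6.0, window=2.0
        )
        low, high = sweep.iloc[0], sweep.iloc[1]
        se = np.hypot(low["force_se"], high["force_se"])
        assert high["force"] - low["force"] > 3 * se

    def test_grid_bounds_enforced(self, set1):
        with pytest.raises(ValueError):
            run_pca_sweep(set1, [3.5], n_traj=2, seed=1)
        with pytest.raises(ValueError):
            run_pca_sweep(set1, [], n_traj=2, seed=1)


class TestTwitchMetrics:
    def test_triangular_pulse_closed_form(self):
        t = np.arange(0.0, 0.4001, 1e-3)
        f = np.interp(t, [0.0, 0.1, 0.3, 0.4], [0.0, 1.0, 0.0, 0.0])
        m = twitch_metrics(np.column_stack([t, f]), stimulus_time=0.0)
        assert m.f_peak == pytest.approx(1.0, abs=1e-9)
        assert m.ttp == pytest.approx(0.100, abs=2e-3)
        assert m.rt50 == pytest.approx(0.100, abs=2e-3)
        assert m.nfti == pytest.approx(0.150, abs=2e-3)
        assert m.rt50_defined

    def test_amplitude_scaling_leaves_timing_invariant(self):
        t = np.arange(0.0, 0.4001, 1e-3)
        f = np.interp(t, [0.0, 0.1, 0.3, 0.4], [0.0, 1.0, 0.0, 0.0])
        m1 = twitch_metrics(np.column_stack([t, f]))
        m2 = twitch_metrics(np.column_stack([t, 2 * f]))
        assert m2.f_peak == pytest.approx(2 * m1.f_peak, rel=1e-9)
        for attr in ("ttp", "rt50", "nfti"):
            assert getattr(m2, attr) == pytest.approx(getattr(m1, attr), rel=1e-9)

    def test_incomplete_relaxation_is_flagged_not_raised(self):
        t = np.arange(0.0, 0.2001, 1e-3)
        f = np.interp(t, [0.0, 0.1, 0.3], [0.0, 1.0, 0.8])  # never halves
        m = twitch_metrics(np.column_stack([t, f]))
        assert not m.rt50_defined
        assert np.isnan(m.rt50)

    def test_baseline_from_prestimulus_window(self):
        t = np.arange(-0.05, 0.3001, 1e-3)
        f = np.where(t < 0, 0.2, 0.2 + np.interp(t, [0.0, 0.1, 0.3], [0, 1.0, 0]))
        m = twitch_metrics(np.column_stack([t, f]), stimulus_time=0.0)
        assert m.baseline == pytest.approx(0.2, abs=1e-9)
        assert m.f_peak == pytest.approx(1.0, abs=1e-2)


class TestSimulateTwitch:
    def test_single_repeat_equals_plain_ensemble(self, set2):
        tr = CaTransient(duration=0.3)
        tw = simulate_twitch(
            set2.with_(n_units=6), tr, n_traj=16, n_repeats=1, seed=5,
            burn_in=0.1, t_pre=0.05,
        )
        ca_fn = make_ca_transient(tr)
        ens = simulate_ensemble(
            set2.with_(n_units=6), lambda t: ca_fn(t - 0.05),
            duration=0.35, n_traj=16, seed=5, burn_in=0.1,
        )
        np.testing.assert_array_equal(tw.force, ens.force)
        np.testing.assert_allclose(tw.time, ens.time - 0.05, atol=1e-12)

    def test_same_master_seed_reproduces_average(self, set2):
        p = set2.with_(n_units=6)
        tr = CaTransient(duration=0.3)
        a = simulate_twitch(p, tr, n_traj=8, n_repeats=3, seed=9, burn_in=0.1)
        b = simulate_twitch(p, tr, n_traj=8, n_repeats=3, seed=9, burn_in=0.1)
        np.testing.assert_array_equal(a.force, b.force)
        assert a.seeds == b.seeds and len(a.seeds) == 3

    def test_wildtype_twitch_relaxes_to_baseline(self, set2):
        tr = CaTransient(duration=1.5)
        tw = simulate_twitch(set2, tr, n_traj=128, n_repeats=1, seed=7)
        m = twitch_metrics(tw)
        end = tw.force[-1]
        end_se = tw.force_se[-1]
        assert abs(end - m.baseline) < 3 * end_se + 0.01
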