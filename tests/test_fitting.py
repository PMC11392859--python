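"""Tests of grid-search fitting, expression inference and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from thinfil import (
    IvmaTargets,
    TwitchDeltaTargets,
    bootstrap_compare,
    grid_search_ivma,
    infer_expression,
)


def fake_sweep():
    """Deterministic stand-in for an expression sweep (synthetic dose
    response; no simulation)."""
    e = np.linspace(0, 1, 11)
    df = pd.DataFrame(
        {
            "expression": e,
            "f_peak": 0.6 - 0.2 * e,
            "ttp": 0.22 - 0.05 * e,
            "rt50": 0.30 - 0.1 * e + 0.06 * e**2,
            "nfti": 0.48 - 0.15 * e,
        }
    )
    ref = df.iloc[0]
    for col in ("f_peak", "ttp", "rt50", "nfti"):
        df[f"pct_{col}"] = 100 * (df[col] - ref[col]) / ref[col]
    return df


class TestGridSearch:
    def test_single_cell_grid_argmin_is_that_cell(self, set1):
        res = grid_search_ivma(
            set1.with_(n_units=8),
            gamma_scales=[0.6],
            kbc_scales=[0.8],
            targets=IvmaTargets(-0.1, -5.0),
            pca_grid=np.linspace(7.0, 4.5, 6),
            n_traj=2,
            seed=3,
            duration=2.0,
            window=1.0,
        )
        assert res.argmin == (0.6, 0.8)
        assert res.sse_surface.shape == (1, 1)
        assert np.isfinite(res.sse_surface).all()
        assert (res.sse_surface >= 0).all()
        assert len(res.cells) == 1

    def test_empty_or_invalid_axes_rejected(self, set1):
        with pytest.raises(ValueError):
            grid_search_ivma(set1, gamma_scales=[], kbc_scales=[1.0],
                             targets=IvmaTargets(-0.1, -5.0))
        with pytest.raises(ValueError):
            grid_search_ivma(set1, gamma_scales=[-0.5], kbc_scales=[1.0],
                             targets=IvmaTargets(-0.1, -5.0))


class TestInferExpression:
    def test_round_trip_recovers_any_row(self):
        sweep = fake_sweep()
        for _, row in sweep.iloc[::2].iterrows():
            targets = TwitchDeltaTargets(
                pct_f_peak=row["pct_f_peak"],
                pct_rt50=row["pct_rt50"],
                pct_nfti=row["pct_nfti"],
            )
            match = infer_expression(sweep, targets)
            assert match.best_expression == pytest.approx(row["expression"])

    def test_zero_targets_select_wildtype_row(self):
        match = infer_expression(fake_sweep(), TwitchDeltaTargets(0.0, 0.0, 0.0))
        assert match.best_expression == 0.0

    def test_admissible_interval_contains_best_match(self):
        sweep = fake_sweep()
        row = sweep.iloc[4]
        targets = TwitchDeltaTargets(
            pct_f_peak=row["pct_f_peak"],
            pct_rt50=row["pct_rt50"],
            pct_nfti=row["pct_nfti"],
            sem_f_peak=3.0, sem_rt50=3.0, sem_nfti=3.0,
        )
        match = infer_expression(sweep, targets)
        grid = set(sweep["expression"])
        assert set(match.admissible) <= grid
        assert match.best_expression in match.admissible
        assert not match.admissible_empty_flag

    def test_unreachable_targets_flag_empty_admissible_set(self):
        targets = TwitchDeltaTargets(
            pct_f_peak=-90.0, pct_rt50=-90.0, pct_nfti=-90.0,
            sem_f_peak=0.5, sem_rt50=0.5, sem_nfti=0.5,
        )
        match = infer_expression(fake_sweep(), targets)
        assert match.admissible == []
        assert match.admissible_empty_flag

    def test_short_sweep_rejected(self):
        with pytest.raises(ValueError):
            infer_expression(fake_sweep().iloc[:2], TwitchDeltaTargets(0, 0, 0))


class TestBootstrap:
    def test_identical_groups_center_on_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = bootstrap_compare(vals, vals, n_resamples=2000, seed=1)
        assert res.diff_means == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.degenerate

    def test_default_resample_count_is_ten_thousand(self):
        import inspect

        sig = inspect.signature(bootstrap_compare)
        assert sig.parameters["n_resamples"].default == 10000

    def test_known_effect_detected_in_most_replicates(self):
        rng = np.random.default_rng(2024)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.0, 0.5, 20)
            b = rng.normal(1.0, 0.5, 20)
            res = bootstrap_compare(a, b, n_resamples=1000,
                                    seed=int(rng.integers(2**31)))
            if res.ci_high < 0.0 or res.ci_low > 0.0:
                detected += 1
        assert detected / n_rep >= 0.95

    def test_degenerate_groups_flagged(self):
        res = bootstrap_compare([2.0] * 5, [2.0] * 5, n_resamples=500, seed=3)
        assert res.degenerate
        assert res.ci_low == res.ci_high == res.diff_means == 0.0
        assert np.isnan(res.p_value)

    def test_deterministic_given_seed(self):
        a = [0.1, 0.4, 0.3, 0.9, 0.2]
        b = [0.6, 0.8, 0.7, 1.1, 0.5]
        r1 = bootstrap_compare(a, b, n_resamples=500, seed=7)
        r2 = bootstrap_compare(a, b, n_resamples=500, seed=7)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare([1.0, 2.0], [1.0, 2.0, 3.0])
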