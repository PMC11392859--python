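"""Fitting mutant parameter changes and expression levels to functional data.

The tropomyosin mutant is represented by two multiplicative parameter
changes: ``gamma_scale`` on the chain-stiffness coupling and
``kbc_scale`` on the B<->C equilibrium constant. A grid search over the
two scales matches motility-assay targets (change in pCa50, percent
change in maximum velocity); a sweep over mutant expression fractions
predicts twitch-metric changes; and the expression level is inferred by
matching predicted to measured percent changes in peak force, RT50 and
nFTI.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MutationSpec, ParameterSet, apply_mutation
from .protocols import (
    CaTransient,
    DEFAULT_PCA_GRID,
    HillFitError,
    fit_hill,
    run_pca_sweep,
    simulate_twitch,
    twitch_metrics,
)

__all__ = [
    "IvmaTargets",
    "GridSearchResult",
    "TwitchDeltaTargets",
    "ExpressionMatch",
    "BootstrapResult",
    "grid_search_ivma",
    "expression_sweep",
    "infer_expression",
    "bootstrap_compare",
    "DEFAULT_GAMMA_SCALES",
    "DEFAULT_KBC_SCALES",
    "DEFAULT_EXPRESSIONS",
]

#: Default grid-search axes: ten values each, spanning down to a 90%
#: stiffness drop and a ~40% B<->C equilibrium drop (K_BC 2.3 -> 1.39
#: for the steady-state set).
DEFAULT_GAMMA_SCALES = np.round(np.linspace(0.1, 1.0, 10), 6)
DEFAULT_KBC_SCALES = np.round(np.linspace(1.39 / 2.3, 1.0, 10), 6)

#: Default expression grid: 0 to 100% in 10% steps.
DEFAULT_EXPRESSIONS = np.round(np.linspace(0.0, 1.0, 11), 6)


@dataclass(frozen=True)
class IvmaTargets:
    """Motility-assay fitting targets for the fully mutant filament:
    absolute change in pCa50 (mutant - WT) and percent change in maximum
    velocity."""

    delta_pca50: float
    pct_delta_vmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_pca50) and np.isfinite(self.pct_delta_vmax)):
            raise ValueError("targets must be finite")


@dataclass
class GridSearchResult:
    gamma_scales: np.ndarray
    kbc_scales: np.ndarray
    sse_surface: np.ndarray  # shape (len(gamma_scales), len(kbc_scales))
    argmin: tuple[float, float]
    cells: pd.DataFrame  # long format: one row per grid cell
    wt_fit: "object"

    def to_long(self) -> pd.DataFrame:
        """Heat-map-ready long format (gamma_scale, kbc_scale, sse, ...)."""
        return self.cells.copy()


def _sweep_and_fit(params, pca_grid, n_traj, seed, duration, window, sample_dt):
    sweep = run_pca_sweep(
        params, pca_grid, n_traj=n_traj, seed=seed,
        duration=duration, window=window, sample_dt=sample_dt,
    )
    return fit_hill(sweep[["pca", "force"]]), sweep


def grid_search_ivma(
    wt: ParameterSet,
    gamma_scales=DEFAULT_GAMMA_SCALES,
    kbc_scales=DEFAULT_KBC_SCALES,
    targets: IvmaTargets | None = None,
    pca_grid=DEFAULT_PCA_GRID,
    n_traj: int = 1920,
    seed: int = 0,
    duration: float = 10.0,
    window: float = 2.5,
    sample_dt: float = 1e-3,
) -> GridSearchResult:
    """Grid search over (gamma_scale, kbc_scale) matching IVMA targets.

    Every cell runs a steady-state pCa sweep with the scaled parameters,
    fits the Hill equation, and scores the squared error of its
    (delta pCa50, % delta Vmax) against ``targets``, each term divided
    by the squared target magnitude so the two heterogeneous components
    are commensurate. Cells whose Hill fit fails score infinity and the
    search continues. Returns the full SSE surface and its argmin.
    """
    gamma_scales = np.asarray(gamma_scales, dtype=float)
    kbc_scales = np.asarray(kbc_scales, dtype=float)
    if gamma_scales.size == 0 or kbc_scales.size == 0:
        raise ValueError("grid axes must be nonempty")
    if np.any(gamma_scales <= 0) or np.any(kbc_scales <= 0):
        raise ValueError("scales must be > 0")
    if targets is None:
        raise ValueError("targets are required")

    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(gamma_scales.size * kbc_scales.size + 1)
    wt_fit, _ = _sweep_and_fit(
        wt, pca_grid, n_traj, int(cell_seeds[0]), duration, window, sample_dt
    )

    w_d = targets.delta_pca50**2 if targets.delta_pca50 != 0 else 1.0
    w_v = targets.pct_delta_vmax**2 if targets.pct_delta_vmax != 0 else 1.0
    sse = np.full((gamma_scales.size, kbc_scales.size), np.inf)
    rows = []
    k = 1
    for i, gs in enumerate(gamma_scales):
        for j, ks in enumerate(kbc_scales):
            params = apply_mutation(
                wt, MutationSpec(gamma_scale=gs, kbc_scale=ks, expression=1.0)
            )
            row = {"gamma_scale": gs, "kbc_scale": ks}
            try:
                fit, _ = _sweep_and_fit(
                    params, pca_grid, n_traj, int(cell_seeds[k]),
                    duration, window, sample_dt,
                )
            except HillFitError as exc:
                warnings.warn(f"cell ({gs}, {ks}) marked invalid: {exc}", stacklevel=2)
                row.update(
                    pca50=np.nan, f_max=np.nan, n_h=np.nan,
                    delta_pca50=np.nan, pct_delta_vmax=np.nan, sse=np.inf,
                )
            else:
                d_pca50 = fit.pca50 - wt_fit.pca50
                pct_dv = 100.0 * (fit.f_max - wt_fit.f_max) / wt_fit.f_max
                cell_sse = (
                    (d_pca50 - targets.delta_pca50) ** 2 / w_d
                    + (pct_dv - targets.pct_delta_vmax) ** 2 / w_v
                )
                sse[i, j] = cell_sse
                row.update(
                    pca50=fit.pca50, f_max=fit.f_max, n_h=fit.n_h,
                    delta_pca50=d_pca50, pct_delta_vmax=pct_dv, sse=cell_sse,
                )
            rows.append(row)
            k += 1
    if not np.isfinite(sse).any():
        raise RuntimeError("all grid cells failed; no valid SSE surface")
    i_min, j_min = np.unravel_index(np.argmin(sse), sse.shape)
    return GridSearchResult(
        gamma_scales=gamma_scales,
        kbc_scales=kbc_scales,
        sse_surface=sse,
        argmin=(float(gamma_scales[i_min]), float(kbc_scales[j_min])),
        cells=pd.DataFrame(rows),
        wt_fit=wt_fit,
    )


# ---------------------------------------------------------------------------
# Expression sweep and inference

_METRIC_COLS = ("f_peak", "ttp", "rt50", "nfti")


def expression_sweep(
    wt: ParameterSet,
    full_mut: MutationSpec,
    expressions=DEFAULT_EXPRESSIONS,
    transient: CaTransient | None = None,
    n_traj: int = 1920,
    n_repeats: int = 10,
    seed: int = 0,
    sample_dt: float = 1e-3,
    burn_in: float = 0.5,
) -> pd.DataFrame:
    """Twitch metrics across mutant expression fractions.

    ``full_mut`` carries the parameter scalings for 100% expression;
    each grid value interpolates linearly between wild type and that
    endpoint. Returns one row per expression with the four twitch
    metrics and their percent changes against the expression-0 row.
    """
    expressions = np.asarray(expressions, dtype=float)
    if np.any(expressions < 0) or np.any(expressions > 1):
        raise ValueError("expressions must lie in [0, 1]")
    if not np.isclose(expressions, 0.0).any():
        raise ValueError("the expression grid must include 0 (the WT reference)")
    if transient is None:
        transient = CaTransient()
    seeds = np.random.SeedSequence(seed).generate_state(expressions.size)
    rows = []
    for e, s in zip(expressions, seeds):
        spec = MutationSpec(
            gamma_scale=full_mut.gamma_scale,
            kbc_scale=full_mut.kbc_scale,
            expression=float(e),
        )
        params = apply_mutation(wt, spec)
        trace = simulate_twitch(
            params, transient, n_traj=n_traj, n_repeats=n_repeats,
            seed=int(s), sample_dt=sample_dt, burn_in=burn_in,
        )
        m = twitch_metrics(trace)
        rows.append(
            {
                "expression": float(e),
                "f_peak": m.f_peak, "ttp": m.ttp, "rt50": m.rt50, "nfti": m.nfti,
                "rt50_defined": m.rt50_defined,
            }
        )
    df = pd.DataFrame(rows).sort_values("expression", ignore_index=True)
    ref = df.loc[df["expression"] == 0.0].iloc[0]
    for col in _METRIC_COLS:
        df[f"pct_{col}"] = 100.0 * (df[col] - ref[col]) / ref[col]
    return df


@dataclass(frozen=True)
class TwitchDeltaTargets:
    """Measured mutant-vs-WT percent changes in twitch metrics (means,
    optionally with standard-error half-widths). TTP is not used for
    inference and is therefore not part of the targets."""

    pct_f_peak: float
    pct_rt50: float
    pct_nfti: float
    sem_f_peak: float | None = None
    sem_rt50: float | None = None
    sem_nfti: float | None = None

    def __post_init__(self) -> None:
        for v in (self.pct_f_peak, self.pct_rt50, self.pct_nfti):
            if not np.isfinite(v):
                raise ValueError("targets must be finite")

    @property
    def has_sem(self) -> bool:
        return None not in (self.sem_f_peak, self.sem_rt50, self.sem_nfti)


@dataclass
class ExpressionMatch:
    """Result of expression inference: the grid expression minimizing
    the (equal-weight) SSE of the three percent-change predictions, the
    per-expression SSE, and — when SEM half-widths were supplied — the
    admissible expressions where every prediction falls inside
    mean +/- SEM (empty and flagged when no expression qualifies)."""

    best_expression: float
    sse: pd.Series
    admissible: list[float]
    admissible_empty_flag: bool


def infer_expression(sweep: pd.DataFrame, targets: TwitchDeltaTargets) -> ExpressionMatch:
    """Infer the mutant expression level from twitch-metric changes.

    ``sweep`` is the output of :func:`expression_sweep`. The best match
    minimizes the equally weighted SSE between predicted and target
    percent changes in peak force, RT50 and nFTI.
    """
    if len(sweep) < 3:
        raise ValueError("sweep must contain at least 3 expression levels")
    pred = sweep[["pct_f_peak", "pct_rt50", "pct_nfti"]].to_numpy(float)
    tgt = np.array([targets.pct_f_peak, targets.pct_rt50, targets.pct_nfti])
    sse = ((pred - tgt) ** 2).sum(axis=1)
    sse_s = pd.Series(sse, index=sweep["expression"].to_numpy(), name="sse")
    best = float(sweep["expression"].iloc[int(np.argmin(sse))])

    admissible: list[float] = []
    flag = False
    if targets.has_sem:
        sem = np.array([targets.sem_f_peak, targets.sem_rt50, targets.sem_nfti])
        inside = (np.abs(pred - tgt) <= sem).all(axis=1)
        admissible = [float(e) for e in sweep["expression"].to_numpy()[inside]]
        flag = len(admissible) == 0
    return ExpressionMatch(
        best_expression=best, sse=sse_s, admissible=admissible,
        admissible_empty_flag=flag,
    )


# ---------------------------------------------------------------------------
# Bootstrap group comparison


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap of the difference in group means (a - b)."""

    diff_means: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False


def bootstrap_compare(
    group_a,
    group_b,
    n_resamples: int = 10000,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile-bootstrap comparison of two groups of metric values.

    Resamples each group with replacement ``n_resamples`` times and
    reports the observed difference in means, the central ``ci``
    percentile interval of the bootstrap differences, and a two-sided
    p-estimate (twice the smaller tail fraction of bootstrap differences
    beyond zero, floored at 2/n_resamples). Deterministic given ``seed``.
    Groups with zero spread yield a zero-width CI and a flagged NaN p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    diff = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_resamples, a.size))
    idx_b = rng.integers(0, b.size, size=(n_resamples, b.size))
    boot = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    if a.std() == 0.0 and b.std() == 0.0:
        return BootstrapResult(diff, diff, diff, float("nan"), degenerate=True)
    p_lo = float(np.mean(boot <= 0.0))
    p_hi = float(np.mean(boot >= 0.0))
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    p = max(p, 2.0 / n_resamples)
    return BootstrapResult(diff, float(lo), float(hi), p, degenerate=False)
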