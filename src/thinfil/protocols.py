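"""Experiment protocols: steady-state force-pCa sweeps with Hill fitting,
and isometric twitches driven by a parametric Ca2+ transient.

Force is the model's mean M-state fraction. For motility-assay
comparisons the maximum steady-state force stands in for maximum sliding
velocity (velocity is taken as approximately proportional to the number
of attached crossbridges).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .model import ParameterSet
from .simulate import TraceEnsemble, simulate_ensemble

__all__ = [
    "HillFit",
    "HillFitError",
    "CaTransient",
    "TwitchMetrics",
    "TwitchTrace",
    "run_pca_sweep",
    "fit_hill",
    "make_ca_transient",
    "simulate_twitch",
    "twitch_metrics",
    "DEFAULT_PCA_GRID",
]

#: Default steady-state grid: 21 points spanning the sigmoid, pCa 7.0 -> 4.5.
DEFAULT_PCA_GRID = np.round(np.linspace(7.0, 4.5, 21), 4)


def pca_to_um(pca: np.ndarray | float) -> np.ndarray | float:
    """Convert pCa (-log10 molar) to free Ca2+ in uM."""
    return 10.0 ** (6.0 - np.asarray(pca, dtype=float))


# ---------------------------------------------------------------------------
# Hill fitting


class HillFitError(RuntimeError):
    """Raised when force/velocity-pCa data cannot support a Hill fit."""


@dataclass(frozen=True)
class HillFit:
    """Hill-equation fit of a force(or velocity)-pCa relation:
    response = f_max * ca^n_h / (ca^n_h + ca50^n_h), with
    pca50 = -log10(ca50 in molar)."""

    f_max: float
    pca50: float
    n_h: float
    residual_sse: float

    def predict(self, pca: np.ndarray | float) -> np.ndarray | float:
        ca = pca_to_um(pca)
        ca50 = 10.0 ** (6.0 - self.pca50)
        return self.f_max * ca**self.n_h / (ca**self.n_h + ca50**self.n_h)


def _extract_xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        pca = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise ValueError("points must be an (n, 2) table of (pCa, response)")
        pca, y = arr[:, 0], arr[:, 1]
    return pca, y


def fit_hill(points) -> HillFit:
    """Least-squares Hill fit of a (pCa, response) point set.

    Requires at least 4 points with responses on both sides of
    half-activation; flat or all-zero data raises :class:`HillFitError`
    rather than returning a degenerate fit.
    """
    pca, y = _extract_xy(points)
    if len(pca) < 4:
        raise HillFitError("need at least 4 (pCa, response) points")
    y_max = float(np.max(y))
    if y_max <= 0 or np.ptp(y) <= 1e-12 * max(1.0, abs(y_max)):
        raise HillFitError("flat or non-activating data; Hill fit undefined")
    if float(np.min(y)) > 0.75 * y_max:
        raise HillFitError("data do not span half-activation; fit ill-posed")

    ca = np.asarray(pca_to_um(pca), dtype=float)

    def model(ca_um, f_max, log10_ca50, n_h):
        c50n = 10.0 ** (log10_ca50 * n_h)
        can = ca_um**n_h
        return f_max * can / (can + c50n)

    # initial ca50: interpolate pCa at half max on sorted data
    order = np.argsort(pca)[::-1]  # low to high ca
    y_s, pca_s = y[order], pca[order]
    half = y_max / 2.0
    above = np.nonzero(y_s >= half)[0]
    pca50_0 = pca_s[above[0]] if len(above) else float(np.median(pca_s))
    p0 = (y_max, 6.0 - pca50_0, 2.0)
    bounds = ([0.0, -6.0, 0.05], [10.0 * y_max, 6.0, 50.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, ca, y, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
    except (RuntimeError, ValueError) as exc:
        raise HillFitError(f"Hill fit failed to converge: {exc}") from exc
    f_max, log10_ca50, n_h = (float(v) for v in popt)
    resid = y - model(ca, *popt)
    sse = float(np.dot(resid, resid))
    if not np.isfinite(sse):
        raise HillFitError("Hill fit produced non-finite residuals")
    return HillFit(f_max=f_max, pca50=6.0 - log10_ca50, n_h=n_h, residual_sse=sse)


# ---------------------------------------------------------------------------
# Steady-state force-pCa protocol


def run_pca_sweep(
    params: ParameterSet,
    pca_grid=DEFAULT_PCA_GRID,
    n_traj: int = 1920,
    seed: int = 0,
    duration: float = 10.0,
    window: float = 2.5,
    sample_dt: float = 1e-3,
    drift_tol_se: float = 3.0,
) -> pd.DataFrame:
    """Steady-state force at each pCa: a ``duration``-second constant-Ca
    simulation, time-averaged over the final ``window`` seconds.

    Returns a DataFrame with columns ``pca``, ``force``, ``force_se``
    (Monte-Carlo standard error of the window mean) and ``drift_flag``
    (True when the two halves of the averaging window differ by more
    than ``drift_tol_se`` standard errors, indicating non-convergence;
    a warning is also emitted).
    """
    pca_grid = np.asarray(pca_grid, dtype=float)
    if pca_grid.size == 0:
        raise ValueError("pca_grid must be nonempty")
    if np.any(pca_grid < 4.0) or np.any(pca_grid > 9.0):
        raise ValueError("pCa values must lie in [4, 9]")
    seeds = np.random.SeedSequence(seed).generate_state(pca_grid.size)
    rows = []
    t0 = duration - window
    for pca, s in zip(pca_grid, seeds):
        ens = simulate_ensemble(
            params, float(pca_to_um(pca)), duration=duration,
            sample_dt=sample_dt, n_traj=n_traj, seed=int(s),
        )
        f, se = ens.window_mean(t0)
        f1, se1 = ens.window_mean(t0, t0 + window / 2)
        f2, se2 = ens.window_mean(t0 + window / 2)
        drift_se = math.hypot(se1, se2)
        drift = bool(abs(f2 - f1) > drift_tol_se * drift_se) if drift_se > 0 else False
        if drift:
            warnings.warn(
                f"pCa {pca}: force drifts across the averaging window "
                f"({f1:.4f} -> {f2:.4f}); steady state may not be reached",
                stacklevel=2,
            )
        rows.append({"pca": pca, "force": f, "force_se": se, "drift_flag": drift})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ca transient and twitch protocol


@dataclass(frozen=True)
class CaTransient:
    """Parametric intracellular Ca2+ transient: a difference-of-
    exponentials pulse rising from the diastolic level to ``peak`` uM at
    ``time_to_peak`` seconds after the stimulus, then decaying with time
    constant ``decay_tau`` back toward the diastolic level."""

    diastolic: float = 0.1
    peak: float = 1.0
    time_to_peak: float = 0.05
    decay_tau: float = 0.15
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.peak <= self.diastolic:
            raise ValueError("peak must exceed diastolic")
        if self.diastolic < 0:
            raise ValueError("diastolic must be >= 0")
        if not (0 < self.time_to_peak < self.duration):
            raise ValueError("need 0 < time_to_peak < duration")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")


def solve_rise_tau(time_to_peak: float, decay_tau: float) -> float:
    """Rise time constant of exp(-t/decay_tau) - exp(-t/rise_tau) whose
    maximum falls at ``time_to_peak``. Requires time_to_peak < decay_tau
    (the peak of the difference pulse always precedes the decay time)."""
    if not 0 < time_to_peak < decay_tau:
        raise ValueError("time_to_peak must lie in (0, decay_tau)")

    def t_peak(tau_r: float) -> float:
        return math.log(decay_tau / tau_r) / (1.0 / tau_r - 1.0 / decay_tau)

    lo = 1e-9 * decay_tau
    hi = (1.0 - 1e-9) * decay_tau
    return float(brentq(lambda tr: t_peak(tr) - time_to_peak, lo, hi, xtol=1e-15))


def make_ca_transient(spec: CaTransient):
    """Build the Ca2+ waveform time -> uM for a twitch (stimulus at t=0;
    the diastolic level holds for t <= 0). The pulse starts exactly at
    ``diastolic`` and attains ``peak`` exactly at ``time_to_peak``; a
    warning is emitted if it has not returned to within 2% of diastolic
    by ``duration``."""
    tau_r = solve_rise_tau(spec.time_to_peak, spec.decay_tau)
    tau_d = spec.decay_tau

    def shape(t):
        return math.exp(-t / tau_d) - math.exp(-t / tau_r)

    s_peak = shape(spec.time_to_peak)
    amp = (spec.peak - spec.diastolic) / s_peak

    def ca_of_t(t: float) -> float:
        if t <= 0.0:
            return spec.diastolic
        return spec.diastolic + amp * shape(t)

    end_dev = abs(ca_of_t(spec.duration) - spec.diastolic)
    if end_dev > 0.02 * spec.diastolic:
        warnings.warn(
            f"Ca transient has not relaxed to diastolic by t={spec.duration}s "
            f"(residual {end_dev:.3g} uM); consider a longer duration",
            stacklevel=2,
        )
    return ca_of_t


@dataclass
class TwitchTrace:
    """Averaged isometric twitch force trace. Time is in seconds with the
    stimulus at t=0; samples at negative times are the pre-stimulus
    diastolic baseline."""

    time: np.ndarray
    force: np.ndarray
    force_se: np.ndarray
    stimulus_time: float
    seeds: list[int]
    n_traj: int
    sample_dt: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "force": self.force, "force_se": self.force_se}
        )


def simulate_twitch(
    params: ParameterSet,
    transient: CaTransient | None = None,
    n_traj: int = 1920,
    n_repeats: int = 10,
    seed: int = 0,
    sample_dt: float = 1e-3,
    burn_in: float = 0.5,
    t_pre: float = 0.05,
) -> TwitchTrace:
    """Isometric twitch: equilibrate the chain at the diastolic Ca2+ for
    ``burn_in`` seconds, record a ``t_pre`` pre-stimulus baseline, then
    drive the Ca transient. The returned trace is the mean of
    ``n_repeats`` independent ensembles of ``n_traj`` trajectories each
    (repeat seeds are spawned from ``seed``; with ``n_repeats=1`` the
    master seed is used directly, making the call identical to a single
    ``simulate_ensemble``)."""
    if transient is None:
        transient = CaTransient()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    ca_fn = make_ca_transient(transient)

    def ca_shifted(t: float) -> float:
        return ca_fn(t - t_pre)

    duration = transient.duration + t_pre
    if n_repeats == 1:
        seeds = [int(seed)]
    else:
        seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_repeats)]
    forces = []
    ses = []
    time = None
    for s in seeds:
        ens = simulate_ensemble(
            params, ca_shifted, duration=duration, sample_dt=sample_dt,
            n_traj=n_traj, seed=s, burn_in=burn_in,
        )
        forces.append(ens.force)
        ses.append(ens.force_se)
        time = ens.time
    force = np.mean(forces, axis=0)
    force_se = np.sqrt(np.sum(np.square(ses), axis=0)) / n_repeats
    return TwitchTrace(
        time=time - t_pre, force=force, force_se=force_se,
        stimulus_time=0.0, seeds=seeds, n_traj=n_traj, sample_dt=sample_dt,
    )


# ---------------------------------------------------------------------------
# Twitch metrics


@dataclass(frozen=True)
class TwitchMetrics:
    """Summary of one twitch: peak force above baseline (model force
    units), time from stimulus to peak (s), time from peak to 50%
    relaxation toward baseline (s; NaN with ``rt50_defined=False`` when
    the record never decays that far), and normalized force-time
    integral (s): area above baseline from stimulus to end of record
    divided by peak force."""

    f_peak: float
    ttp: float
    rt50: float
    nfti: float
    baseline: float
    rt50_defined: bool = True


def _trace_arrays(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, TwitchTrace):
        return trace.time, trace.force
    if isinstance(trace, TraceEnsemble):
        return trace.time, trace.force
    if isinstance(trace, pd.DataFrame):
        return trace["time"].to_numpy(float), trace["force"].to_numpy(float)
    arr = np.asarray(trace, dtype=float)
    if arr.ndim == 2 and arr.shape[1] >= 2:
        return arr[:, 0], arr[:, 1]
    raise ValueError("trace must be a TwitchTrace, DataFrame or (n, 2) array")


def twitch_metrics(
    trace,
    stimulus_time: float = 0.0,
    baseline_window: float = 0.05,
    smooth_window: float | None = None,
) -> TwitchMetrics:
    """Extract :class:`TwitchMetrics` from a time/force trace.

    The baseline is the mean force over the ``baseline_window`` seconds
    preceding the stimulus (falling back to the first sample when there
    is no pre-stimulus record). The trace is linearly interpolated onto
    a uniform grid at its median sampling interval before extraction;
    the 50%-relaxation time is located by linear interpolation between
    the bracketing samples.

    ``smooth_window`` (seconds) applies a quadratic Savitzky-Golay
    filter of that width before extraction — recommended for noisy
    single-trace records, where the raw argmax otherwise wanders over
    the flat peak; it is exact for locally quadratic peaks and so
    introduces negligible bias at twitch timescales.
    """
    t_raw, f_raw = _trace_arrays(trace)
    if len(t_raw) < 3:
        raise ValueError("trace too short")
    if np.any(np.diff(t_raw) <= 0):
        raise ValueError("trace time must be strictly increasing")
    dt = float(np.median(np.diff(t_raw)))
    t = np.arange(t_raw[0], t_raw[-1] + 0.5 * dt, dt)
    f = np.interp(t, t_raw, f_raw)
    if smooth_window is not None:
        from scipy.signal import savgol_filter

        w = max(5, int(round(smooth_window / dt)) | 1)
        if w < len(f):
            f = savgol_filter(f, w, polyorder=2)

    pre = (t >= stimulus_time - baseline_window) & (t < stimulus_time)
    baseline = float(f[pre].mean()) if pre.any() else float(f[0])

    post = t >= stimulus_time
    if not post.any():
        raise ValueError("trace does not cover the stimulus")
    tp, fp = t[post], f[post]
    i_peak = int(np.argmax(fp))
    f_peak = float(fp[i_peak] - baseline)
    ttp = float(tp[i_peak] - stimulus_time)
    if f_peak <= 0:
        return TwitchMetrics(0.0, ttp, float("nan"), 0.0, baseline, False)

    half = baseline + 0.5 * f_peak
    rt50 = float("nan")
    rt50_defined = False
    below = np.nonzero(fp[i_peak:] <= half)[0]
    if len(below):
        j = i_peak + below[0]
        if j == i_peak:
            rt50 = 0.0
        else:
            frac = (fp[j - 1] - half) / (fp[j - 1] - fp[j])
            rt50 = float(tp[j - 1] + frac * (tp[j] - tp[j - 1]) - tp[i_peak])
        rt50_defined = True

    nfti = float(np.trapezoid(fp - baseline, tp) / f_peak)
    return TwitchMetrics(f_peak, ttp, rt50, nfti, baseline, rt50_defined)
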