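"""Synthetic assay data with the statistical structure the pipeline assumes.

Two generators replace the wet-lab inputs: noisy motility-assay
velocity-pCa point sets (a Hill curve plus additive i.i.d. Gaussian
noise) and noisy engineered-heart-tissue twitch traces (a smooth
sigmoidal-rise/exponential-decay pulse parameterized by root-finding
time-to-peak and half-relaxation time, plus additive Gaussian noise).
Both are deterministic given their seed, so every downstream fitting
stage has an exactly reproducible parameter-recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq



__all__ = [
    "SyntheticIvmaSpec",
    "SyntheticTwitchSpec",
    "gen_ivma_points",
    "gen_twitch_trace",
    "biexp_taus_for",
]

_DEFAULT_PCA_POINTS = tuple(np.round(np.linspace(7.0, 4.5, 21), 4))


@dataclass(frozen=True)
class SyntheticIvmaSpec:
    """Generating parameters for a velocity-pCa point set: Hill curve
    (v_max, pca50, n_h) evaluated on ``pca_points`` with additive
    Gaussian noise of standard deviation ``noise_sd``."""

    v_max: float = 1.0
    pca50: float = 6.0
    n_h: float = 3.0
    noise_sd: float = 0.0
    pca_points: tuple = _DEFAULT_PCA_POINTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.n_h <= 0:
            raise ValueError("v_max and n_h must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        pts = np.asarray(self.pca_points, dtype=float)
        if pts.size < 4 or not (pts.min() < self.pca50 < pts.max()):
            raise ValueError("pca_points must span the half-activation point")


def gen_ivma_points(spec: SyntheticIvmaSpec) -> pd.DataFrame:
    """Synthetic motility-assay points: DataFrame (pca, velocity)."""
    pca = np.asarray(spec.pca_points, dtype=float)
    ca = 10.0 ** (6.0 - pca)
    ca50 = 10.0 ** (6.0 - spec.pca50)
    v = spec.v_max * ca**spec.n_h / (ca**spec.n_h + ca50**spec.n_h)
    rng = np.random.default_rng(spec.seed)
    v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    return pd.DataFrame({"pca": pca, "velocity": v})


# ---------------------------------------------------------------------------
# Twitch traces


#: Sharpness of the sigmoidal rise of the synthetic twitch shape.
_RISE_POWER = 4


def _twitch_shape(t, tau_r: float, tau_d: float):
    """Sigmoidal-rise / exponential-decay pulse
    (1 - exp(-t/tau_r))**4 * exp(-t/tau_d); flexible enough to place the
    half-relaxation time anywhere from ~0.2x to many times the
    time-to-peak (a pure difference of exponentials cannot relax faster
    than ~1.7x its time-to-peak)."""
    t = np.asarray(t, dtype=float)
    s = (1.0 - np.exp(-t / tau_r)) ** _RISE_POWER * np.exp(-t / tau_d)
    return np.where(t > 0, s, 0.0)


def _shape_peak_time(tau_r: float, tau_d: float) -> float:
    # root of d/dt log s: p*exp(-t/tau_r)/(tau_r*(1-exp(-t/tau_r))) = 1/tau_d
    def g(t: float) -> float:
        x = math.exp(-t / tau_r)
        return _RISE_POWER * x / (tau_r * (1.0 - x)) - 1.0 / tau_d

    lo, hi = 1e-9 * tau_r, _RISE_POWER * tau_d * (1 + tau_r)
    while g(hi) > 0:  # pragma: no cover - defensive widening
        hi *= 2
    return float(brentq(g, lo, hi, xtol=1e-15))


def _rt50_of(tau_r: float, tau_d: float) -> float:
    """Half-relaxation time of the pulse after its peak."""
    t_peak = _shape_peak_time(tau_r, tau_d)
    s_half = 0.5 * float(_twitch_shape(t_peak, tau_r, tau_d))
    hi = t_peak + tau_d
    while float(_twitch_shape(hi, tau_r, tau_d)) > s_half:
        hi += tau_d
        if hi > t_peak + 1000 * tau_d:  # pragma: no cover - defensive
            raise RuntimeError("half-relaxation search did not converge")
    t_half = brentq(
        lambda t: float(_twitch_shape(t, tau_r, tau_d)) - s_half,
        t_peak, hi, xtol=1e-14,
    )
    return float(t_half) - t_peak


def _rise_tau_for_peak(ttp: float, tau_d: float) -> float:
    """Rise constant placing the pulse peak at ``ttp`` for given decay."""
    # peak time grows monotonically with tau_r, from 0 towards p*tau_d
    lo, hi = 1e-7 * ttp, 500.0 * (ttp + tau_d)
    f_lo = _shape_peak_time(lo, tau_d) - ttp
    f_hi = _shape_peak_time(hi, tau_d) - ttp
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"no rise constant places the peak at {ttp} s")
    return float(brentq(lambda tr: _shape_peak_time(tr, tau_d) - ttp, lo, hi,
                        xtol=1e-15))


def biexp_taus_for(ttp: float, rt50: float) -> tuple[float, float]:
    """Rise and decay time constants of the synthetic twitch pulse whose
    peak falls at ``ttp`` and whose post-peak half-decay takes ``rt50``.
    Raises ValueError when no such pulse exists (rt50 far too short or
    too long relative to ttp)."""
    if ttp <= 0 or rt50 <= 0:
        raise ValueError("ttp and rt50 must be > 0")

    def g(tau_d: float) -> float:
        tau_r = _rise_tau_for_peak(ttp, tau_d)
        return _rt50_of(tau_r, tau_d) - rt50

    # the peak time cannot exceed _RISE_POWER * tau_d, so decay constants
    # below ttp/_RISE_POWER cannot place the peak at ttp at all
    lo = 1.1 * ttp / _RISE_POWER
    hi = 100.0 * (ttp + rt50)
    g_lo, g_hi = g(lo), g(hi)
    if g_lo > 0:
        raise ValueError(
            f"rt50={rt50} too short for ttp={ttp}: the sharpest admissible "
            f"pulse already relaxes no faster than {rt50 + g_lo:.4g}"
        )
    if g_hi < 0:  # pragma: no cover - enormous rt50/ttp ratios only
        raise ValueError(f"rt50={rt50} too long for ttp={ttp}")
    tau_d = brentq(g, lo, hi, xtol=1e-12)
    return _rise_tau_for_peak(ttp, tau_d), float(tau_d)


@dataclass(frozen=True)
class SyntheticTwitchSpec:
    """Target shape of a synthetic isometric twitch record: peak force
    ``f_peak`` above ``baseline``, stimulus-to-peak time ``ttp`` and
    half-relaxation time ``rt50`` (seconds), sampled every ``sample_dt``
    over ``duration`` with ``t_pre`` seconds of pre-stimulus baseline;
    additive Gaussian noise of standard deviation ``noise_sd``."""

    f_peak: float = 1.0
    ttp: float = 0.15
    rt50: float = 0.15
    baseline: float = 0.0
    noise_sd: float = 0.0
    sample_dt: float = 1e-3
    duration: float = 1.0
    t_pre: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_peak <= 0:
            raise ValueError("f_peak must be > 0")
        if not 0 < self.ttp < self.duration:
            raise ValueError("need 0 < ttp < duration")
        if self.rt50 <= 0 or self.ttp + self.rt50 >= self.duration:
            raise ValueError("peak + rt50 must fall inside the record")
        if self.noise_sd < 0 or self.sample_dt <= 0:
            raise ValueError("noise_sd >= 0 and sample_dt > 0 required")
        if self.ttp < 2 * self.sample_dt or self.rt50 < 2 * self.sample_dt:
            raise ValueError("ttp and rt50 must each span >= 2 sample steps")


def gen_twitch_trace(spec: SyntheticTwitchSpec) -> pd.DataFrame:
    """Synthetic twitch record: DataFrame (time, force) with the stimulus
    at time 0. Noiseless metrics match the spec targets to within one
    sample step."""
    tau_r, tau_d = biexp_taus_for(spec.ttp, spec.rt50)
    s_peak = float(_twitch_shape(spec.ttp, tau_r, tau_d))
    t = np.arange(-spec.t_pre, spec.duration + 0.5 * spec.sample_dt, spec.sample_dt)
    f = spec.baseline + spec.f_peak * _twitch_shape(t, tau_r, tau_d) / s_peak
    rng = np.random.default_rng(spec.seed)
    f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)
    return pd.DataFrame({"time": t, "force": f})
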