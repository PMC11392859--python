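"""Stochastic simulation of the coupled regulatory-unit chain.

The chain of ``n_units`` regulatory units (default 26) is simulated as a
continuous-time Markov process. The exact event-driven (Gillespie) engine
samples the next transition from the chain's current total rate, with the
neighbor-dependent tropomyosin rates recomputed for the two neighbors of
each changed unit; a fixed-step engine (per-step transition probability
``1 - exp(-k dt)``) is provided for cross-checking. Force is the fraction
of units with tropomyosin in the M (myosin-bound) position.

Time-varying Ca2+ is handled by holding the concentration constant within
each sampling bin, which is exact for the steady-state protocols and
introduces negligible bias for twitch transients sampled at ~1 ms.

``master_equation_force`` solves the full joint-state master equation for
chains of up to 3 units and serves as an independent oracle for the
stochastic engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .model import ParameterSet, TpmPos, enumerate_states, transition_rate

__all__ = [
    "TraceEnsemble",
    "simulate_ensemble",
    "master_equation_force",
    "master_equation_stationary",
    "single_unit_rate_table",
]

_N_STATES = 24
_N_SLOTS = 5  # ca toggle, sp toggle, ip toggle, tpm down, tpm up

# index of all-off, tpm=B, ip bound: ca=0 sp=0 ip=1 tpm=B
_INIT_STATE = 1 * 3 + 0


def _decode(s: int) -> tuple[int, int, int, int]:
    return s // 12, (s // 6) % 2, (s // 3) % 2, s % 3


def _transition_targets() -> np.ndarray:
    """target[s, slot] = destination state index, -1 if the slot is
    inactive in state s. Slots: 0 Ca toggle, 1 SP toggle, 2 IP toggle,
    3 tpm position down, 4 tpm position up."""
    tgt = np.full((_N_STATES, _N_SLOTS), -1, dtype=np.int64)
    for s in range(_N_STATES):
        ca, sp, ip, tpm = _decode(s)
        tgt[s, 0] = s + (12 if ca == 0 else -12)
        tgt[s, 1] = s + (6 if sp == 0 else -6)
        tgt[s, 2] = s + (3 if ip == 0 else -3)
        if tpm > 0:
            tgt[s, 3] = s - 1
        if tpm < 2:
            tgt[s, 4] = s + 1
    return tgt


_TARGETS = _transition_targets()


def _params_vector(p: ParameterSet) -> np.ndarray:
    return np.array(
        [
            p.kCa_plus, p.kCa_minus, p.kSP_plus, p.kSP_minus, p.kIP_plus,
            p.kIP_minus, p.kMD_plus, p.kMD_minus, p.kref_BC, p.K_BC,
            p.f_XY, p.delta, p.lam, p.eta, p.mu, p.coupling_energy,
            1.0 if p.couple_cm else 0.0,
            1.0 if p.lam_gates_cm else 0.0,
            {"ip": 0.0, "tni": 1.0, "switched": 2.0}[p.lam_gate],
            1.0 if p.lam_gates_fxy else 0.0,
            1.0 if p.fxy_on_bc else 0.0,
            1.0 if p.ip_rebind_gated else 0.0,
            (
                0.0 if not p.tni_lock
                else {"all": 1.0, "sp_ip": 2.0, "ip": 3.0}[p.lock_scope]
            ),
        ],
        dtype=np.float64,
    )


@njit(cache=True, inline="always")
def _tni_pins(p, cab, sp, ip):
    """Whether TnI pins tropomyosin (the lam gate applies) in the given
    troponin sub-state, under the configured gate mode."""
    if p[18] == 2.0:  # free only when Ca-switched: ca & sp & !ip
        return not (cab == 1 and sp == 1 and ip == 0)
    if p[18] == 1.0:  # free when switched regardless of Ca: sp & !ip
        return not (sp == 1 and ip == 0)
    return ip == 1  # inhibitory peptide bound


@njit(cache=True, inline="always")
def _base_rates(p, ca, base):
    """Neighbor-independent part of every per-state transition rate at
    Ca2+ concentration ``ca`` (uM); written into base[24, 5]."""
    delta = p[11]
    kbc_f = p[8] * p[9] ** delta
    kbc_b = p[8] * p[9] ** (delta - 1.0)
    for s in range(_N_STATES):
        cab = s // 12
        sp = (s // 6) % 2
        ip = (s // 3) % 2
        tpm = s % 3
        pins_here = _tni_pins(p, cab, sp, ip)
        # Ca toggle
        if cab == 0:
            r = p[0] * ca
        else:
            r = p[1] / p[13] if sp == 1 else p[1]
        if (
            p[22] == 1.0 and tpm != 0 and not pins_here
            and _tni_pins(p, 1 - cab, sp, ip)
        ):
            r *= p[12]
        base[s, 0] = r
        # SP toggle
        if sp == 0:
            r = p[2]
            if cab == 1:
                r *= p[13]
            if ip == 1:
                r /= p[14]
        else:
            r = p[3]
        if (
            0.0 < p[22] <= 2.0 and tpm != 0 and not pins_here
            and _tni_pins(p, cab, 1 - sp, ip)
        ):
            r *= p[12]
        base[s, 1] = r
        # IP toggle
        if ip == 0:
            r = p[4] / p[14] if sp == 1 else p[4]
            if p[21] > 0.0 and tpm != 0:  # actin site occluded unless Tpm in B
                r *= p[12]
        else:
            r = p[5]
        if (
            p[22] > 0.0 and tpm != 0 and not pins_here
            and _tni_pins(p, cab, sp, 1 - ip)
        ):
            r *= p[12]
        base[s, 2] = r
        # tpm; lam applies while TnI pins tropomyosin
        pins = _tni_pins(p, cab, sp, ip)
        if tpm == 0:
            base[s, 3] = 0.0
            base[s, 4] = kbc_f * p[12] if pins else kbc_f
        elif tpm == 1:
            base[s, 3] = kbc_b
            base[s, 4] = p[6]
        else:
            base[s, 3] = p[7]
            base[s, 4] = 0.0


@njit(cache=True, inline="always")
def _unit_rates(p, base, states, i, n_units, periodic, out):
    """Full rates of unit i given current chain configuration."""
    s = states[i]
    for k in range(_N_SLOTS):
        out[k] = base[s, k]
    tpm = s % 3
    # neighbor tpm positions (-1 = absent chain end)
    if i > 0:
        xl = states[i - 1] % 3
    elif periodic and n_units > 1:
        xl = states[n_units - 1] % 3
    else:
        xl = -1
    if i < n_units - 1:
        xr = states[i + 1] % 3
    elif periodic and n_units > 1:
        xr = states[0] % 3
    else:
        xr = -1
    # coupling-energy changes (units of RT) for the two position steps:
    # E(C)-E(B): +1 per B neighbor, -1 per C/M neighbor;
    # E(M)-E(C): +1 per B/C neighbor, -1 per M neighbor.
    de_bc = 0.0
    de_cm = 0.0
    if xl >= 0:
        de_bc += 1.0 if xl == 0 else -1.0
        de_cm += 1.0 if xl <= 1 else -1.0
    if xr >= 0:
        de_bc += 1.0 if xr == 0 else -1.0
        de_cm += 1.0 if xr <= 1 else -1.0
    de_bc *= p[15]
    de_cm *= p[15] * p[16]
    if tpm == 0:
        out[4] *= math.exp(-p[11] * de_bc)
        if p[20] > 0.0:  # crossbridge recruitment of blocked neighbors
            n_m = 0
            if xl == 2:
                n_m += 1
            if xr == 2:
                n_m += 1
            if n_m > 0:
                recruit = p[10] * n_m
                if p[19] > 0.0 and _tni_pins(p, s // 12, (s // 6) % 2, (s // 3) % 2):
                    recruit *= p[12]
                out[4] += recruit
    elif tpm == 1:
        out[3] *= math.exp((1.0 - p[11]) * de_bc)
        n_m = 0
        if xl == 2:
            n_m += 1
        if xr == 2:
            n_m += 1
        attach = out[4] * math.exp(-p[11] * de_cm)
        recruit = p[10] * n_m
        pins = _tni_pins(p, s // 12, (s // 6) % 2, (s // 3) % 2)
        if p[17] > 0.0 and pins:  # lam gates C->M while TnI pins
            attach *= p[12]
            if p[19] > 0.0:
                recruit *= p[12]
        out[4] = attach + recruit
    else:
        out[3] *= math.exp((1.0 - p[11]) * de_cm)


@njit(cache=True)
def _run_trajectory(
    p, n_units, periodic, ca_arr, sample_dt, targets,
    states, rates, base, occ_acc, m_count_out,
):
    """Simulate one trajectory over len(ca_arr) sampling bins, starting
    from the configuration in ``states`` (modified in place). Occupancy
    counts at each bin start are accumulated into occ_acc[n_bins, 24];
    the per-bin M-state unit count is written to m_count_out."""
    n_bins = ca_arr.shape[0]
    ca_prev = -1.0
    for k in range(n_bins):
        ca = ca_arr[k]
        if ca != ca_prev:
            _base_rates(p, ca, base)
            for i in range(n_units):
                _unit_rates(p, base, states, i, n_units, periodic, rates[i])
            ca_prev = ca
        # record at bin start
        m_count = 0
        for i in range(n_units):
            occ_acc[k, states[i]] += 1.0
            if states[i] % 3 == 2:
                m_count += 1
        m_count_out[k] = m_count
        # advance to bin end
        t = k * sample_dt
        t_end = (k + 1) * sample_dt
        while True:
            total = 0.0
            for i in range(n_units):
                for j in range(_N_SLOTS):
                    total += rates[i, j]
            if total <= 0.0:
                break
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            t += -math.log(u) / total
            if t >= t_end:
                break
            r = np.random.random() * total
            acc = 0.0
            i_sel = n_units - 1
            j_sel = _N_SLOTS - 1
            done = False
            for i in range(n_units):
                for j in range(_N_SLOTS):
                    acc += rates[i, j]
                    if acc >= r:
                        i_sel = i
                        j_sel = j
                        done = True
                        break
                if done:
                    break
            s_new = targets[states[i_sel], j_sel]
            if s_new < 0:
                continue
            states[i_sel] = s_new
            lo = i_sel - 1
            hi = i_sel + 1
            for i in range(lo, hi + 1):
                ii = i
                if periodic:
                    ii = i % n_units
                if 0 <= ii < n_units:
                    _unit_rates(p, base, states, ii, n_units, periodic, rates[ii])


@njit(cache=True)
def _run_trajectory_fixed(
    p, n_units, periodic, ca_arr, sample_dt, dt, targets,
    states, rates, base, occ_acc, m_count_out,
):
    """Fixed-step variant: at each step of size dt every unit makes a
    transition with probability 1 - exp(-k_exit dt). Returns the largest
    per-step exit probability seen (for step-size validation)."""
    n_bins = ca_arr.shape[0]
    steps_per_bin = max(1, int(round(sample_dt / dt)))
    ca_prev = -1.0
    max_p = 0.0
    for k in range(n_bins):
        ca = ca_arr[k]
        if ca != ca_prev:
            _base_rates(p, ca, base)
            ca_prev = ca
        m_count = 0
        for i in range(n_units):
            occ_acc[k, states[i]] += 1.0
            if states[i] % 3 == 2:
                m_count += 1
        m_count_out[k] = m_count
        for _ in range(steps_per_bin):
            for i in range(n_units):
                _unit_rates(p, base, states, i, n_units, periodic, rates[i])
            for i in range(n_units):
                k_exit = 0.0
                for j in range(_N_SLOTS):
                    k_exit += rates[i, j]
                if k_exit <= 0.0:
                    continue
                p_jump = 1.0 - math.exp(-k_exit * dt)
                if p_jump > max_p:
                    max_p = p_jump
                if np.random.random() < p_jump:
                    r = np.random.random() * k_exit
                    acc = 0.0
                    j_sel = _N_SLOTS - 1
                    for j in range(_N_SLOTS):
                        acc += rates[i, j]
                        if acc >= r:
                            j_sel = j
                            break
                    s_new = targets[states[i], j_sel]
                    if s_new >= 0:
                        states[i] = s_new
    return max_p


@njit(cache=True)
def _ensemble_kernel(
    p, n_units, periodic, ca_arr, sample_dt, seeds, fixed_dt,
    occ_acc, traj_force, init_states,
):
    targets = _transition_targets_nb()
    n_traj = seeds.shape[0]
    rates = np.zeros((n_units, _N_SLOTS))
    base = np.zeros((_N_STATES, _N_SLOTS))
    m_count = np.zeros(ca_arr.shape[0], dtype=np.int64)
    max_p = 0.0
    for j in range(n_traj):
        np.random.seed(seeds[j])
        states = init_states.copy()
        if fixed_dt > 0.0:
            mp = _run_trajectory_fixed(
                p, n_units, periodic, ca_arr, sample_dt, fixed_dt, targets,
                states, rates, base, occ_acc, m_count,
            )
            if mp > max_p:
                max_p = mp
        else:
            _run_trajectory(
                p, n_units, periodic, ca_arr, sample_dt, targets,
                states, rates, base, occ_acc, m_count,
            )
        for k in range(ca_arr.shape[0]):
            traj_force[j, k] = m_count[k] / n_units
    return max_p


@njit(cache=True)
def _transition_targets_nb():
    tgt = np.full((_N_STATES, _N_SLOTS), -1, dtype=np.int64)
    for s in range(_N_STATES):
        ca = s // 12
        sp = (s // 6) % 2
        ip = (s // 3) % 2
        tpm = s % 3
        tgt[s, 0] = s + (12 if ca == 0 else -12)
        tgt[s, 1] = s + (6 if sp == 0 else -6)
        tgt[s, 2] = s + (3 if ip == 0 else -3)
        if tpm > 0:
            tgt[s, 3] = s - 1
        if tpm < 2:
            tgt[s, 4] = s + 1
    return tgt


@dataclass
class TraceEnsemble:
    """Ensemble-averaged trajectory of the chain.

    ``force`` is the mean fraction of units in the M state at each time;
    ``occupancy`` the mean fraction of units in each of the 24 states
    (rows sum to 1); ``force_se`` the Monte-Carlo standard error of the
    ensemble mean force per time point; ``traj_force`` the per-trajectory
    M fraction (n_traj x n_times), kept for window-averaged statistics.
    """

    time: np.ndarray
    force: np.ndarray
    occupancy: np.ndarray
    force_se: np.ndarray
    traj_force: np.ndarray
    n_traj: int
    seed: int

    def to_frame(self, occupancy: bool = False):
        """Trace as a DataFrame (time, force, force_se[, occ_00..occ_23])."""
        import pandas as pd

        df = pd.DataFrame(
            {"time": self.time, "force": self.force, "force_se": self.force_se}
        )
        if occupancy:
            for s in range(self.occupancy.shape[1]):
                df[f"occ_{s:02d}"] = self.occupancy[:, s]
        return df

    def window_mean(self, t_start: float, t_end: float | None = None) -> tuple[float, float]:
        """Time-averaged force over [t_start, t_end] and its Monte-Carlo
        standard error (computed across per-trajectory window means)."""
        mask = self.time >= t_start
        if t_end is not None:
            mask &= self.time <= t_end
        if not mask.any():
            raise ValueError("empty averaging window")
        w = self.traj_force[:, mask].mean(axis=1)
        se = w.std(ddof=1) / math.sqrt(len(w)) if len(w) > 1 else float("nan")
        return float(w.mean()), float(se)


_MAX_STEP_PROB = 0.25


def simulate_ensemble(
    params: ParameterSet,
    ca_of_t: Callable[[float], float] | float,
    duration: float,
    sample_dt: float = 1e-3,
    n_traj: int = 1920,
    seed: int = 0,
    burn_in: float = 0.0,
    method: str = "exact",
    fixed_dt: float = 2e-5,
) -> TraceEnsemble:
    """Simulate ``n_traj`` independent chains and average them.

    Parameters
    ----------
    ca_of_t
        Free Ca2+ concentration in uM: a constant or a function of time
        (seconds, stimulus at t=0). During ``burn_in`` seconds preceding
        t=0 the chain equilibrates at ``ca_of_t(0)``; the burn-in is not
        part of the returned trace.
    method
        ``"exact"`` (event-driven, default) or ``"fixed"`` (fixed time
        step ``fixed_dt``; raises if any per-step jump probability
        exceeds 0.25, naming the offending rate).

    Returns a :class:`TraceEnsemble`; identical inputs and seed reproduce
    the trace bit-identically. Trajectory RNG streams are spawned from
    ``seed`` via ``numpy.random.SeedSequence`` in trajectory order.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if method not in ("exact", "fixed"):
        raise ValueError("method must be 'exact' or 'fixed'")

    n_rec = int(round(duration / sample_dt))
    n_burn = int(round(burn_in / sample_dt))
    time = (np.arange(n_rec) * sample_dt)

    if callable(ca_of_t):
        ca_rec = np.array([float(ca_of_t(t)) for t in time])
    else:
        ca_rec = np.full(n_rec, float(ca_of_t))
    if np.any(ca_rec < 0) or not np.all(np.isfinite(ca_rec)):
        raise ValueError("ca_of_t must be finite and >= 0")
    ca0 = float(ca_of_t(0.0)) if callable(ca_of_t) else float(ca_of_t)
    ca_arr = np.concatenate([np.full(n_burn, ca0), ca_rec])

    p = _params_vector(params)
    n_units = params.n_units
    seeds = np.random.SeedSequence(seed).generate_state(n_traj).astype(np.int64)
    n_bins = n_burn + n_rec
    occ_acc = np.zeros((n_bins, _N_STATES))
    traj_force = np.zeros((n_traj, n_bins))
    init_states = np.full(n_units, _INIT_STATE, dtype=np.int64)

    fdt = fixed_dt if method == "fixed" else -1.0
    max_p = _ensemble_kernel(
        p, n_units, params.periodic, ca_arr, sample_dt, seeds, fdt,
        occ_acc, traj_force, init_states,
    )
    if method == "fixed" and max_p > _MAX_STEP_PROB:
        k_eff = -math.log(1.0 - max_p) / fixed_dt
        raise ValueError(
            f"fixed-step inconsistency: per-step jump probability {max_p:.3f} "
            f"(effective exit rate {k_eff:.1f} s^-1) exceeds {_MAX_STEP_PROB}; "
            f"reduce fixed_dt below {_MAX_STEP_PROB / k_eff:.2e} s"
        )

    occ = occ_acc[n_burn:] / (n_traj * n_units)
    tf = traj_force[:, n_burn:]
    force = tf.mean(axis=0)
    if n_traj > 1:
        force_se = tf.std(axis=0, ddof=1) / math.sqrt(n_traj)
    else:
        force_se = np.full(n_rec, np.nan)
    return TraceEnsemble(
        time=time, force=force, occupancy=occ, force_se=force_se,
        traj_force=tf, n_traj=n_traj, seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact master-equation oracle (small chains)


def single_unit_rate_table(params: ParameterSet, ca: float) -> np.ndarray:
    """rate[s, s', lcode, rcode] for all single-unit transitions, where
    neighbor codes 0/1/2 are B/C/M and 3 means no neighbor. Built from
    the pure-Python :func:`thinfil.model.transition_rate`, independently
    of the compiled simulation kernel."""
    states = enumerate_states()
    nbr_opts = [TpmPos.B, TpmPos.C, TpmPos.M, None]
    out = np.zeros((_N_STATES, _N_STATES, 4, 4))
    for s in states:
        for j in range(_N_SLOTS):
            t_idx = _TARGETS[s.index, j]
            if t_idx < 0:
                continue
            t = states[t_idx]
            for li, ln in enumerate(nbr_opts):
                for ri, rn in enumerate(nbr_opts):
                    out[s.index, t_idx, li, ri] = transition_rate(
                        s, t, ln, rn, params, ca
                    )
    return out


def _nbr_code(joint: int, pos: int, n_units: int) -> int:
    if pos < 0 or pos >= n_units:
        return 3
    return (joint // (24**pos)) % 24 % 3


def master_equation_stationary(
    params: ParameterSet, ca: float, n_units: int
) -> np.ndarray:
    """Stationary distribution over the 24**n_units joint states of a
    small chain, solved exactly from the master equation."""
    if n_units < 1 or n_units > 3:
        raise ValueError("master equation tractable only for 1 <= n_units <= 3")
    if ca < 0:
        raise ValueError("ca must be >= 0")
    table = single_unit_rate_table(params, ca)
    n_joint = 24**n_units
    rows, cols, vals = [], [], []
    for joint in range(n_joint):
        for i in range(n_units):
            s_i = (joint // (24**i)) % 24
            lc = _nbr_code(joint, i - 1, n_units)
            rc = _nbr_code(joint, i + 1, n_units)
            for j in range(_N_SLOTS):
                t_idx = _TARGETS[s_i, j]
                if t_idx < 0:
                    continue
                rate = table[s_i, t_idx, lc, rc]
                if rate <= 0.0:
                    continue
                target = joint + (t_idx - s_i) * (24**i)
                rows.append(joint)
                cols.append(target)
                vals.append(rate)
    q = sparse.coo_matrix((vals, (rows, cols)), shape=(n_joint, n_joint)).tocsr()
    diag = np.asarray(q.sum(axis=1)).ravel()
    q = q - sparse.diags(diag)
    # solve pi Q = 0 with normalisation replacing the last column of Q^T
    a = q.T.tolil()
    a[-1, :] = 1.0
    b = np.zeros(n_joint)
    b[-1] = 1.0
    if n_joint <= 1000:
        pi = np.linalg.solve(a.toarray(), b)
    else:
        pi = spsolve(a.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def master_equation_force(params: ParameterSet, ca: float, n_units: int) -> float:
    """Steady-state expected fraction of units in the M state, from the
    exact stationary distribution of the joint master equation."""
    pi = master_equation_stationary(params, ca, n_units)
    n_joint = 24**n_units
    joint = np.arange(n_joint)
    m_count = np.zeros(n_joint)
    for i in range(n_units):
        m_count += ((joint // (24**i)) % 24) % 3 == 2
    return float(np.dot(pi, m_count) / n_units)
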