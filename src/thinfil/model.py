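"""Core 24-state regulatory-unit model of the cardiac thin filament.

Each regulatory unit (one troponin/tropomyosin span, ~7 actin monomers)
is described by four components:

* ``ca_bound`` — Ca2+ occupancy of the TnC regulatory site,
* ``sp_bound`` — TnI switch peptide docked on the TnC N-lobe,
* ``ip_bound`` — TnI inhibitory peptide bound to actin,
* ``tpm_pos``  — azimuthal tropomyosin position: blocked (B), closed (C)
  or open/myosin-bound (M).

The product space 2 x 2 x 2 x 3 gives the 24 states. Units are coupled in
series through tropomyosin's end-to-end overlap: a unit's tropomyosin
transition rates depend on the positions of its nearest neighbors through
an elastic coupling energy scaled by the effective chain stiffness
``gamma``, and myosin binding (C->M, and escape from B next to bound
myosin) is accelerated by neighbors already in M through the crossbridge
recruitment rate ``f_XY``.

Ca2+ regulates the chain through troponin: tropomyosin of a unit whose
troponin is not fully switched (Ca on TnC, switch peptide docked,
inhibitory peptide off actin) can only shift forward at a small leak
rate (factor ``lam``), and, conversely, while tropomyosin is away from
the blocked position the troponin transitions that would re-pin it are
attenuated by the same factor (``lam`` is the statistical weight of the
pinned-troponin / non-blocked-tropomyosin configuration; the barrier is
placed on the pinning side). Alternative gating schemes are selectable
through :class:`ParameterSet` flags.
"""

from __future__ import annotations

import enum
import importlib.resources
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = [
    "TpmPos",
    "RegulatoryUnitState",
    "ParameterSet",
    "MutationSpec",
    "enumerate_states",
    "transition_rate",
    "apply_mutation",
    "load_parameter_set",
    "save_parameter_set",
    "RT_J_PER_MOL",
]

#: Thermal energy RT in J/mol at ~300 K (for reference; the coupling
#: energy is handled dimensionlessly, in units of RT).
RT_J_PER_MOL = 2494.0


class TpmPos(enum.IntEnum):
    """Azimuthal tropomyosin position; the integer value is the position
    index x used by the neighbor-coupling energy (B=0, C=1, M=2)."""

    B = 0
    C = 1
    M = 2


@dataclass(frozen=True, order=True)
class RegulatoryUnitState:
    ca_bound: bool
    sp_bound: bool
    ip_bound: bool
    tpm_pos: TpmPos

    @property
    def index(self) -> int:
        """Position of this state in the frozen lexicographic order
        (ca_bound, sp_bound, ip_bound, tpm_pos)."""
        return (
            (int(self.ca_bound) * 2 + int(self.sp_bound)) * 2 + int(self.ip_bound)
        ) * 3 + int(self.tpm_pos)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca_bound", bool(self.ca_bound))
        object.__setattr__(self, "sp_bound", bool(self.sp_bound))
        object.__setattr__(self, "ip_bound", bool(self.ip_bound))
        object.__setattr__(self, "tpm_pos", TpmPos(self.tpm_pos))


_STATES: tuple[RegulatoryUnitState, ...] = tuple(
    RegulatoryUnitState(bool(ca), bool(sp), bool(ip), TpmPos(tpm))
    for ca in (0, 1)
    for sp in (0, 1)
    for ip in (0, 1)
    for tpm in (0, 1, 2)
)


def enumerate_states() -> list[RegulatoryUnitState]:
    """All 24 per-unit states in frozen lexicographic order
    (ca_bound, sp_bound, ip_bound, tpm_pos); ``state.index`` gives the
    position of a state in this list."""
    return list(_STATES)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and coupling coefficients for one genotype condition.

    Rates are s^-1 except ``kCa_plus`` (uM^-1 s^-1). ``gamma`` is the
    tropomyosin chain-stiffness coupling, a dimensionless statistical
    weight per unit of azimuthal position difference between neighbors:
    each nearest-neighbor pair contributes a coupling energy
    ``ln(gamma) * |x_i - x_j|`` (in units of RT, optionally rescaled by
    ``coupling_scale``), so e.g. a unit flanked by two like-positioned
    neighbors pays ``2 ln(gamma)`` RT to move one position away from
    them; ``gamma = 1`` decouples the chain. ``K_BC`` is the
    B->C / C->B rate ratio absent TnI inhibition; ``delta`` places the
    B<->C transition barrier (and splits the coupling energy between the
    forward and backward rates); ``lam`` is the forbidden-configuration
    weight through which troponin pins tropomyosin (see module
    docstring); ``eta`` and ``mu`` are the Ca-switch and
    switch-inhibitory thermodynamic couplings within troponin; ``f_XY``
    is the per-M-neighbor crossbridge recruitment rate.

    Scheme flags (defaults give the package's standard model):

    * ``couple_cm`` — apply the chain-stiffness factor to C<->M as well
      as B<->C (True) or to B<->C only (False).
    * ``lam_gate`` — troponin condition that frees tropomyosin:
      ``"switched"`` (Ca and switch peptide on, inhibitory peptide off;
      default), ``"tni"`` (switch on, inhibitory off), or ``"ip"``
      (inhibitory peptide off).
    * ``tni_lock`` / ``lock_scope`` — whether (and for which troponin
      components) transitions re-pinning the troponin of an active
      (non-B) unit pay the ``lam`` weight; required by detailed balance
      when ``lam`` is read as a configuration energy.
    * ``lam_gates_cm`` / ``lam_gates_fxy`` / ``fxy_on_bc`` — whether the
      gate covers C->M, whether it covers the f_XY recruitment term, and
      whether recruitment also assists B->C of blocked neighbors.
    """

    kCa_plus: float
    kCa_minus: float
    kSP_plus: float
    kSP_minus: float
    kIP_plus: float
    kIP_minus: float
    kMD_plus: float
    kMD_minus: float
    kref_BC: float
    K_BC: float
    f_XY: float
    delta: float
    lam: float
    eta: float
    mu: float
    gamma: float
    n_units: int = 26
    coupling_scale: float = 1.0
    periodic: bool = False
    couple_cm: bool = True
    lam_gates_cm: bool = True
    lam_gate: str = "switched"
    lam_gates_fxy: bool = True
    fxy_on_bc: bool = True
    ip_rebind_gated: bool = False
    tni_lock: bool = True
    lock_scope: str = "all"

    def __post_init__(self) -> None:
        for name in (
            "kCa_plus", "kCa_minus", "kSP_plus", "kSP_minus", "kIP_plus",
            "kIP_minus", "kMD_plus", "kMD_minus", "kref_BC", "f_XY",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.K_BC <= 0:
            raise ValueError("K_BC must be > 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")
        if self.eta < 1.0 or self.mu < 1.0:
            raise ValueError("eta and mu must be >= 1")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0 (1 decouples the chain)")
        if self.coupling_scale < 0:
            raise ValueError("coupling_scale must be >= 0")
        if self.lam_gate not in ("ip", "tni", "switched"):
            raise ValueError("lam_gate must be 'ip', 'tni' or 'switched'")
        if self.lock_scope not in ("all", "sp_ip", "ip"):
            raise ValueError("lock_scope must be 'all', 'sp_ip' or 'ip'")

    def tpm_lock_exempt(self, component: str) -> bool:
        """Whether a troponin component is exempt from the active-
        tropomyosin lock (see ``lock_scope``)."""
        if self.lock_scope == "all":
            return False
        if self.lock_scope == "sp_ip":
            return component == "ca"
        return component != "ip"  # scope "ip"

    @property
    def coupling_energy(self) -> float:
        """Dimensionless coupling energy (units of RT) per unit of
        neighbor position mismatch: coupling_scale * ln(gamma)."""
        return self.coupling_scale * math.log(self.gamma)

    def with_(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MutationSpec:
    """Multiplicative perturbation of the tropomyosin parameters by a
    mutant allele expressed at a given fraction.

    At ``expression`` = e the perturbed parameter p becomes
    ``p * (1 - e + e * scale)`` — linear interpolation between the
    wild-type value (e = 0) and the fully mutant value (e = 1).
    """

    gamma_scale: float = 1.0
    kbc_scale: float = 1.0
    expression: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_scale <= 0 or self.kbc_scale <= 0:
            raise ValueError("mutation scales must be > 0")
        if not 0.0 <= self.expression <= 1.0:
            raise ValueError("expression must lie in [0, 1]")


def apply_mutation(wt: ParameterSet, spec: MutationSpec) -> ParameterSet:
    """Interpolate gamma and K_BC between wild-type and fully mutant
    values in proportion to the mutant expression fraction."""
    e = spec.expression
    return replace(
        wt,
        gamma=wt.gamma * (1.0 - e + e * spec.gamma_scale),
        K_BC=wt.K_BC * (1.0 - e + e * spec.kbc_scale),
    )


def _neighbor_coupling_delta_e(
    x_from: int,
    x_to: int,
    left_nbr: TpmPos | None,
    right_nbr: TpmPos | None,
    coupling_energy: float,
) -> float:
    """Coupling-energy change (units of RT) when tropomyosin moves from
    position x_from to x_to, given the neighbor positions. Each present
    neighbor contributes coupling_energy * |x_self - x_nbr|; absent neighbors
    (chain ends) contribute nothing."""
    de = 0.0
    for nbr in (left_nbr, right_nbr):
        if nbr is None:
            continue
        xn = int(nbr)
        de += abs(x_to - xn) - abs(x_from - xn)
    return coupling_energy * de


def transition_rate(
    frm: RegulatoryUnitState,
    to: RegulatoryUnitState,
    left_nbr: TpmPos | None,
    right_nbr: TpmPos | None,
    params: ParameterSet,
    ca: float,
) -> float:
    """Instantaneous rate (s^-1) of the single-component transition
    ``frm -> to`` for a unit with the given neighbor tropomyosin
    positions at free Ca2+ concentration ``ca`` (uM).

    Only transitions changing exactly one component have nonzero rate;
    the direct B<->M tropomyosin jump is forbidden. Tropomyosin position
    changes carry the nearest-neighbor Boltzmann factor: with
    coupling-energy change dE = (gamma/RT) * d(sum |x_self - x_nbr|) for
    the forward (position-increasing) move, the forward rate is
    multiplied by exp(-delta*dE) and the backward rate by
    exp((1-delta)*dE), so e.g. the B->C / C->B rate ratio is
    K_BC * exp(-dE) for every neighbor configuration. With
    ``params.couple_cm`` False the factor is restricted to B<->C.
    """
    if ca < 0:
        raise ValueError("ca must be >= 0")
    if frm == to:
        raise ValueError("frm and to must differ")

    diffs = (
        (frm.ca_bound != to.ca_bound)
        + (frm.sp_bound != to.sp_bound)
        + (frm.ip_bound != to.ip_bound)
        + (frm.tpm_pos != to.tpm_pos)
    )
    if diffs != 1:
        return 0.0

    p = params

    def pins(state: RegulatoryUnitState) -> bool:
        if p.lam_gate == "ip":
            return state.ip_bound
        if p.lam_gate == "tni":
            return not (state.sp_bound and not state.ip_bound)
        return not (state.ca_bound and state.sp_bound and not state.ip_bound)

    def lock_factor(component: str) -> float:
        # pinning-energy counterpart on the troponin side: entering a
        # pinning configuration while tropomyosin is away from B pays lam
        # (only for the troponin components in lock_scope)
        if not p.tni_lock or p.tpm_lock_exempt(component):
            return 1.0
        if frm.tpm_pos != TpmPos.B and not pins(frm) and pins(to):
            return p.lam
        return 1.0
    if frm.ca_bound != to.ca_bound:
        if to.ca_bound:
            return p.kCa_plus * ca * lock_factor("ca")
        return p.kCa_minus / (p.eta if frm.sp_bound else 1.0) * lock_factor("ca")

    if frm.sp_bound != to.sp_bound:
        if to.sp_bound:
            rate = p.kSP_plus
            if frm.ca_bound:
                rate *= p.eta
            if frm.ip_bound:
                rate /= p.mu
            return rate * lock_factor("sp")
        return p.kSP_minus * lock_factor("sp")

    if frm.ip_bound != to.ip_bound:
        if to.ip_bound:
            rate = p.kIP_plus / (p.mu if frm.sp_bound else 1.0)
            if p.ip_rebind_gated and frm.tpm_pos != TpmPos.B:
                rate *= p.lam  # IP's actin site occluded unless Tpm is blocked
            return rate * lock_factor("ip")
        return p.kIP_minus * lock_factor("ip")

    # tropomyosin move
    x0, x1 = int(frm.tpm_pos), int(to.tpm_pos)
    if abs(x1 - x0) != 1:
        return 0.0  # direct B<->M forbidden
    if p.lam_gate == "ip":
        tni_pins = frm.ip_bound
    elif p.lam_gate == "tni":
        tni_pins = not (frm.sp_bound and not frm.ip_bound)
    else:  # "switched": Tpm free only in the Ca-switched troponin state
        tni_pins = not (frm.ca_bound and frm.sp_bound and not frm.ip_bound)
    if x0 == 0 and x1 == 1:  # B -> C
        de = _neighbor_coupling_delta_e(0, 1, left_nbr, right_nbr, p.coupling_energy)
        rate = p.kref_BC * p.K_BC**p.delta * math.exp(-p.delta * de)
        recruit = 0.0
        if p.fxy_on_bc:  # crossbridge recruitment of blocked neighbors
            recruit = p.f_XY * sum(
                1 for nbr in (left_nbr, right_nbr) if nbr == TpmPos.M
            )
        if tni_pins:
            rate *= p.lam
            if p.lam_gates_fxy:
                recruit *= p.lam
        return rate + recruit
    if x0 == 1 and x1 == 0:  # C -> B
        de = _neighbor_coupling_delta_e(0, 1, left_nbr, right_nbr, p.coupling_energy)
        return p.kref_BC * p.K_BC ** (p.delta - 1.0) * math.exp((1.0 - p.delta) * de)
    de_cm = (
        _neighbor_coupling_delta_e(1, 2, left_nbr, right_nbr, p.coupling_energy)
        if p.couple_cm
        else 0.0
    )
    if x0 == 1 and x1 == 2:  # C -> M, crossbridge-assisted
        n_m = sum(1 for nbr in (left_nbr, right_nbr) if nbr == TpmPos.M)
        attach = p.kMD_plus * math.exp(-p.delta * de_cm)
        recruit = p.f_XY * n_m
        if tni_pins and p.lam_gates_cm:
            attach *= p.lam
            if p.lam_gates_fxy:
                recruit *= p.lam
        return attach + recruit
    # M -> C
    return p.kMD_minus * math.exp((1.0 - p.delta) * de_cm)


# ---------------------------------------------------------------------------
# Parameter-set I/O and packaged fixtures

_PARAM_KEYS = [f.name for f in fields(ParameterSet)]


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a flat key-value JSON file."""
    data = {name: getattr(params, name) for name in _PARAM_KEYS}
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _from_mapping(data: dict) -> ParameterSet:
    unknown = set(data) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ParameterSet(**data)


def load_parameter_set(name_or_path: str | Path) -> ParameterSet:
    """Load a parameter set from a JSON file, or one of the packaged
    fixtures ``"set1"`` (steady-state) / ``"set2"`` (twitch kinetics)."""
    name = str(name_or_path)
    if name in ("set1", "set2"):
        ref = importlib.resources.files("thinfil").joinpath(f"params/{name}.json")
        return _from_mapping(json.loads(ref.read_text()))
    return _from_mapping(json.loads(Path(name_or_path).read_text()))
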