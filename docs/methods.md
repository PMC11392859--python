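# Methods

## The model

The thin filament is represented as a linear chain of 26 regulatory
units (RUs), each one troponin–tropomyosin span covering ~7 actin
monomers. An RU occupies one of 24 states, the product of four
components:

| component | meaning | values |
|---|---|---|
| `ca_bound` | Ca²⁺ on the TnC regulatory site | 0/1 |
| `sp_bound` | TnI switch peptide docked on the TnC N-lobe | 0/1 |
| `ip_bound` | TnI inhibitory peptide bound to actin | 0/1 |
| `tpm_pos` | azimuthal tropomyosin position | B (blocked, x=0), C (closed, x=1), M (myosin-bound, x=2) |

Force is the fraction of units in M. States are ordered
lexicographically by (`ca_bound`, `sp_bound`, `ip_bound`, `tpm_pos`);
the order is frozen and exposed as `RegulatoryUnitState.index`.

### Rate law

All transitions change exactly one component; the direct B↔M jump is
forbidden. Troponin transitions follow mass action with two
thermodynamic couplings: η links Ca to the switch peptide (SP binding
×η when Ca is bound, Ca unbinding ÷η when SP is bound) and μ makes SP
and IP binding mutually antagonistic (each ÷μ when the other is bound).
Both couplings appear once per interaction, so every troponin 4-cycle
satisfies detailed balance exactly; the test suite asserts this at
machine precision in every context.

Tropomyosin moves between adjacent positions with

- B→C: `kref_BC · K_BC^δ`, C→B: `kref_BC · K_BC^(δ−1)` — the ratio is
  `K_BC`, with δ placing the transition barrier;
- C→M: `kMD_plus`, M→C: `kMD_minus` (a driven, ATP-consuming step, not
  subject to detailed balance).

**Nearest-neighbor coupling.** Adjacent tropomyosins interact through
the end-to-end overlap. Each neighbor pair contributes a coupling
energy `J·|x_i − x_j|` (units of RT), where `J =
coupling_scale·ln(γ)` and γ is the dimensionless chain-stiffness
weight. A position change with energy change ΔE multiplies the forward
rate by `exp(−δ·ΔE)` and the backward rate by `exp((1−δ)·ΔE)` (the same
barrier split as for `K_BC`), so the equilibrium shift is exactly
`exp(−ΔE)` for every neighbor configuration. The factor acts on B↔C and
(by default) C↔M. Chain ends have one neighbor; a missing neighbor
contributes zero energy (periodic boundaries are available by flag).

**Crossbridge feedback.** A bound myosin (M-state neighbor) adds
`f_XY` per such neighbor to the C→M rate of its neighbors and, by
default, to their B→C rate as well — the classic crossbridge-mediated
cooperative recruitment.

**Ca²⁺ gating (λ).** Tropomyosin of a unit whose troponin is not fully
switched — i.e. not (Ca bound ∧ SP docked ∧ IP released) — can only
shift forward (B→C, C→M, including the recruitment term) at a small
leak rate: the rate is multiplied by λ. λ is read as the Boltzmann
weight of the "pinned troponin with non-blocked tropomyosin"
configuration; detailed balance of that energy then requires the
complementary factor on the troponin side, so while tropomyosin is in
C or M, troponin transitions that would *enter* a pinning configuration
(Ca unbinding, SP undocking, IP rebinding from the switched state) are
also multiplied by λ, with the barrier placed entirely on the pinning
side. Functionally this means Ca controls the *onset* of activation,
and an activated unit holds its switched troponin until tropomyosin
returns to B — a kinetic rectification that is essential for twitch
behavior (see "Design choices").

### Parameters

Two packaged parameter sets (`set1` for steady-state force–pCa work,
`set2` for twitch kinetics) carry the rate constants, the couplings
η, μ, the equilibrium `K_BC` (2.3 / 2.0), the barrier position δ
(0.48 / 0.4), the leak λ (8×10⁻³ / 10⁻⁴), the recruitment rate `f_XY`
(225 / 25 s⁻¹), and the chain-stiffness weight γ (70 / 50) with a
per-set `coupling_scale` fixing the wild-type coupling energy at
J ≈ 1.43 RT (`set1`) and J ≈ 1.02 RT (`set2`), i.e. the published
energies (3570 and 2550 J/mol at RT = 2494 J/mol). γ = 1 decouples the
chain.

### The mutant

The dilated-cardiomyopathy tropomyosin substitution M8R, located in the
end-to-end overlap, is modeled as two multiplicative changes: the
chain-stiffness weight γ ×0.5 (70→35; a ~16% drop in coupling energy)
and `K_BC` ×0.74 (2.3→1.70), i.e. reduced neighbor coupling plus a bias
toward the blocked position. Partial expression e interpolates each
parameter linearly between wild type (e=0) and full mutant (e=1) —
`p(e) = p·(1−e+e·scale)`.

## Simulation engine

The chain is a continuous-time Markov process; the default engine is
exact event-driven (Gillespie) sampling over the chain's instantaneous
total rate, recomputing the neighbor-dependent rates of the changed
unit and its two neighbors after every event. Time-varying Ca²⁺ is held
constant within each sampling bin (default 1 ms) — exact for constant-Ca
protocols, negligible bias for twitch transients. A fixed-step engine
(per-step probability `1−exp(−k·dt)`, dt = 2×10⁻⁵ s, aborting if any
per-step jump probability exceeds 0.25) is kept for cross-checks. The
kernels are Numba-compiled; one master seed spawns per-trajectory
`SeedSequence` streams in trajectory order, making every ensemble
bit-reproducible.

For chains of ≤3 units the full joint master equation (24ⁿ states) is
solved exactly for the stationary distribution; this is the independent
oracle the stochastic engine is validated against (1- and 2-unit chains
across five Ca levels, 3 Monte-Carlo SE at 2000 trajectories). The
oracle builds its generator from the pure-Python rate function, a
separate code path from the compiled kernel. Because the λ-gated
transitions create ~1 s relaxation modes, steady-state comparisons use
10 s of simulated time (matching the steady-state protocol below).

## Protocols

**Force–pCa.** 10 s of constant Ca per point, force averaged over the
final 2.5 s; default grid 21 points, pCa 7.0→4.5. A drift flag (and
warning) marks points where the two halves of the averaging window
differ by more than 3 SE. The Hill equation
`F = F_max·Ca^n_H/(Ca^n_H + Ca50^n_H)` is fit by bounded least squares
(log₁₀ Ca50 as the free parameter); flat, non-activating or
non-spanning data raise rather than returning a degenerate fit.
Motility-assay maximum velocity is compared through `F_max`, assuming
velocity ∝ steady-state crossbridge (M-state) count.

**Twitch.** The Ca transient is a difference-of-exponentials pulse
rising from diastolic 0.1 μM to a 1.0 μM peak at 50 ms, decaying with
τ = 150 ms over a 1 s record (all configurable); the rise constant is
solved so the peak lands exactly on `time_to_peak`. The chain
equilibrates at diastolic Ca for 0.5 s of burn-in (several times the
slowest diastolic relaxation mode), records a 50 ms pre-stimulus
baseline, and is then driven by the transient. The default ensemble is
1920 trajectories per twitch, composed as 10 independent repeats of 192
averaged together. Metrics: baseline = mean force over the 50 ms before
the stimulus; `F_peak` = max above baseline; TTP = stimulus→peak;
RT50 = peak→50% decay toward baseline (linear interpolation between
bracketing samples; flagged, not raised, when the record never decays
that far); nFTI = area above baseline from stimulus to end ÷ `F_peak`.
Traces are linearly interpolated to a uniform grid first; an optional
Savitzky–Golay smoother (quadratic, window ~50 ms) is recommended for
noisy single-trace records, where raw argmax timing otherwise wanders
by ~5–10 ms at 5% noise.

## Fitting

**Grid search.** For each (γ-scale, K_BC-scale) cell the full
steady-state protocol runs with the scaled parameters; the cell's error
is `((ΔpCa50 − t₁)/t₁)² + ((%ΔVmax − t₂)/t₂)²` — each term normalized
by the squared target so the two heterogeneous components are
commensurate (the weighting of the original analysis is not stated).
Cells whose Hill fit fails score ∞ and the search continues. Default
axes: γ-scale 0.1–1.0, K_BC-scale 0.604–1.0 (K_BC 1.39–2.3), ten values
each.

**Expression inference.** The expression sweep produces percent changes
of the four twitch metrics against the expression-0 row; inference
minimizes the equally weighted SSE of (%ΔF_peak, %ΔRT50, %ΔnFTI)
against measured targets. TTP is reported but excluded from the match.
When SEM half-widths accompany the targets, the admissible set — grid
expressions where all three predictions fall inside mean ± SEM — is
returned alongside (empty and flagged when none qualifies).

**Bootstrap.** Group comparisons use a percentile bootstrap of the
difference in means, 10,000 resamples by default, seeded and
deterministic; degenerate (zero-spread) inputs yield a zero-width CI
and a flagged NaN p-value.

## Synthetic data

Two generators emulate the wet-lab inputs so every fitting stage has an
exact parameter-recovery test: velocity–pCa point sets (Hill curve plus
additive i.i.d. Gaussian noise — no noise model is published for the
assay, so independent Gaussian errors are the neutral choice) and
isometric twitch records (a sigmoidal-rise/exponential-decay pulse
`(1−e^{−t/τ_r})⁴·e^{−t/τ_d}`, its two time constants solved by nested
root-finding so the noiseless peak and half-relaxation land exactly on
the requested TTP and RT50). A pure difference of exponentials cannot
relax faster than ~1.7× its time to peak and so cannot represent
realistic twitch shapes (RT50/TTP ≈ 1 in tissue records and in this
model's own output), which is why the rise is sigmoidal. The generators
produce i.i.d. Gaussian noise only: no baseline drift, pacing
artifacts, filament breakage or heteroscedasticity — passing recovery
tests therefore validates the estimators under clean error structure,
not robustness to structured artifacts.

## Design choices on open ground

The source model's 24-state topology and the exact roles of f_XY, η, μ,
λ and δ are not restated in the text this package reconstructs them
from; the defaults here were selected by requiring the wild-type and
single-parameter phenotypes to behave correctly, and every choice is a
`ParameterSet` flag so alternatives remain reachable:

* **γ as a weight, energy from the published value.** The published
  table prints γ as an energy (3570/2550 J·mol⁻¹) while the narrative
  uses 70→35; the two differ by exactly a factor 51 in both sets. The
  package stores the narrative-scale dimensionless weight (the quantity
  the mutation halves) and calibrates `coupling_scale` so the wild-type
  energy equals the tabulated value per RT. Using ln(70) RT ≈ 4.25 RT as
  the energy instead freezes twitch nucleation entirely, and halving
  the *energy* exaggerates every mutant phenotype.
* **Gate condition.** Gating tropomyosin on IP occupancy alone cannot
  regulate this chain: with the published troponin constants the IP-free
  fraction spans only ~0.33–0.56 (set 1) over the entire physiological
  Ca range, while the base B→C/C→B ratio is ~2 — no sigmoid and no
  twitch results. The fully switched conjunction spans ~10–13×
  between diastole and saturation and is the physiological trigger for
  tropomyosin release; it is the default gate.
* **The troponin-side lock.** Without the reciprocal λ on re-pinning
  transitions, activation is a duty-cycle product (gate ceiling × rate
  ratio < 1) and the kinetic set produces no twitch at all under any
  multiplicative gating. With the lock, Ca controls activation onset
  and the model produces realistic twitches (F_peak ≈ 0.57 of the
  26-unit maximum, TTP ≈ 0.21 s, RT50 ≈ 0.32 s at the defaults).
* **C↔M coupling and recruitment on B→C** are required for a
  cooperatively stable blocked phase at rest and for the active phase
  to survive the mutant K_BC reduction as a sensitivity shift rather
  than collapse.

## Problem sizes

The exact engine simulates the 26-unit chain at ~10⁵ events per second
of model time. The packaged drivers and tests use: 8–16 trajectories
per pCa point (the 2.5 s window average is itself an average over
thousands of correlated samples), 2000 trajectories for oracle
comparisons, the full 1920-trajectory ensemble (192×10) for twitch
sweeps, and a 4×4 coarse grid for the recovery experiment. These sizes
put the full test suite and the acceptance script within minutes on a
single core while keeping every Monte-Carlo tolerance at 3 SE or
tighter.

## Known limitations

* The rate-scheme reconstruction is validated against the published
  *phenotypes*, not against the original implementation; absolute
  quantities (pCa50 ≈ 6.3 for set 1 rather than ~5.5–6 reported for
  regulated motility) shift with the open choices above.
* RT50 and nFTI decrease monotonically with mutant expression in this
  reconstruction (−34%/−31% at 100%); the biphasic fall-then-rise
  reported for the original model does not reproduce — its upturn
  requires relaxation to be dominated by scattered active units at high
  expression, a regime this reconstruction only enters at much deeper
  force loss than 100% expression produces here. Consequently the
  equal-weight best-match expression for the measured tissue phenotype
  lands at 50%, at the upper edge of the expected 30–40% (±10%) window,
  dragged there by the shallow simulated peak-force dose response;
  RT50 and nFTI individually match the measurements at 30–35%.
* The Ca transient is fixed; mutation effects on Ca buffering and
  handling feed back on neither the transient nor the electrophysiology.
* No explicit crossbridge mechanics: M-state occupancy is the force
  proxy, and no sarcomere-length or load dependence exists.
* Expression inference assumes uniform stochastic incorporation of
  mutant tropomyosin via global parameter interpolation, not per-dimer
  mosaicism along the filament.
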