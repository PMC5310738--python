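# Methods

## Model structure and assumptions

A circuit is a set of population-averaged firing-rate nodes coupled by
neuromodulator pathways. Three timescale/structure assumptions define the
model class:

1. **Algebraic rates.** Population firing-rate dynamics (tens of
   milliseconds) are far faster than every neuromodulator-induced process in
   the model (time constants 1–60 s), so rates are slaved to the
   instantaneous currents through the threshold-linear f–I map
   `f = K·[I − I₀ + I_bias]₊`. A projection may instead use the reduced
   "direct-rate" coupling, in which the target's rate is itself a slow
   variable relaxing towards a rate-valued response curve — useful for
   two-region models where the induced-current step adds nothing. Mixing
   both coupling kinds onto one population is rejected at validation, and at
   most one direct-rate projection may target a population (the model gives
   no meaning to summing two "target rates").
2. **One effective current per pathway.** Each (species, source, target)
   triple carries a single induced current relaxing with time constant τ
   towards a sigmoid function of the extracellular concentration. Multiple
   receptor subtypes per pathway, autoreceptors, local interneurons and
   co-released fast transmitters are out of scope.
3. **Well-mixed extracellular pools.** Each pathway has one concentration
   variable driven by the source population's rate, with either
   Michaelis–Menten reuptake (monoamines, where transporter kinetics are
   measured) or linear decay (orexin, where they are not). No diffusion or
   volume transmission.

**Sigmoid convention.** The response curve is a logistic in log₁₀
concentration (nM): `G(c) = p_LR + (p_UR − p_LR)·σ((log₁₀c − p_LS)/p_S)`.
Published shift values near −2 "nM" with sub-unity slopes are only
dimensionally coherent on a log₁₀(nM) abscissa, which is also the standard
dose–response convention; the curve family is an explicit, swappable
choice. Inhibitory responses (the GIRK currents) are encoded by signed
values — there is no separate inhibition flag. Zero concentration is mapped
through a floor of 1e-9 nM before the log, so it evaluates to the lower
asymptote; the floor sits two decades below the smallest concentration the
bundled circuit visits (the fM-scale 5-HT level at the LC, 1.1e-7 nM).

**Degenerate inputs.** `p_LR = p_UR` gives a constant curve (legal);
`slope ≤ 0` and `τ ≤ 0` are validation errors; a Michaelis–Menten pathway
whose release rate `y_p·f` reaches `V_max` has no finite steady state —
the closed-form solver rejects it outright, and the simulator raises once
release exceeds `V_max` *while* the concentration has run past 10·K_m
(transient crossings with bounded concentrations are legitimate dynamics
and occur in the bundled circuit's from-zeros transient).

## Numerics

Forward Euler at dt = 1 ms (default). The fastest rate in the bundled
circuit is the serotonin reuptake linearisation `V_max·K_m/(K_m+c)² ≈
10.6 s⁻¹`, so the explicit-Euler stability bound is ~190 ms; long scans use
dt = 50 ms, still well inside it. Concentrations (and direct-rate rates)
are clamped at zero after each step, since Euler can overshoot when
reuptake is strong. The scheme is first order: the relative error of the
induced-current relaxation at t = τ is ~dt/2τ (1.4e-5 at τ = 20 s,
dt = 1 ms), and the test suite asserts the order-1 scaling of terminal
states against a 16×-finer reference.

**Steady-state criterion.** Convergence requires every |derivative| below a
per-quantity tolerance (defaults 1e-6 nM/s, pA/s, Hz/s) sustained for one
simulated second; the default horizon is 600 s from the basal initial
state (time constants ≤ 60 s). From a cold start the slow mode is the NE
pool at the DRN — its linearised reuptake rate at the 2.95 µM baseline is
~2.6e-3 s⁻¹ (τ ≈ 380 s) — so cold-start and drug-scan runs use a 20 000–
40 000 s horizon at dt = 50 ms (seconds of wall time). Non-convergence is
an explicit error, never a silent partial result. Identical inputs give
bit-identical trajectories.

## The three-region preset

Populations: LHA orexin neurons (K = 0.2 Hz/pA, I₀ = 0, I_bias = 11.5 pA,
basal 2.3 Hz), DRN serotonin neurons (0.033, 24.82, 24.82, 0.8 Hz), LC
norepinephrine neurons (0.058, 0.028, 37.41, 2.15 Hz). Pathways and time
constants: 5-HT→LHA (2 s), 5-HT→LC (20 s), NE→DRN (20 s), NE→LHA (1 s),
Ox→DRN (60 s), Ox→LC (20 s). Uptake kinetics: V_max/K_m = 1800/170 nM·s⁻¹/nM
at all serotonin sites, 74/400 at all NE sites; orexin decays at
η = 0.85 s⁻¹. Basal concentrations: 1.6 nM 5-HT at the LHA, 0.11 fM-scale
5-HT at the LC, 2.95 µM NE at the DRN, 0.83 nM NE at the LHA, 3.4 nM Ox at
the DRN, 0.56 nM Ox at the LC (values published in pg/mg or fM are stored
in nM using their published molar equivalences; display scales are kept in
the bundle's `display_units`).

**Regenerated response curves.** Only the Ox→LC curve is fully published
(3.8→54 pA, shift −2.3, slope 0.341) plus the Ox→DRN shift/slope
(−2.08, 0.452). The remaining curve parameters are solved at build time
from the basal current balances, with shape choices constrained by the
published qualitative descriptions:

* **LHA.** Its bias current alone accounts for the basal rate
  (0.2 × 11.5 = 2.3 Hz), which forces the two inhibitory GIRK curves to
  cross zero exactly at the basal concentrations; their small positive
  low-concentration offsets absorb that anchoring. The 5-HT GIRK saturates
  at −35 pA with its steep section inside the 10–100 nM decade (shift 1.5,
  slope 0.35) — strong enough to silence orexin neurons at micromolar
  5-HT; the NE GIRK saturates at −25 pA (shift 1.2, slope 0.4).
* **LC.** The published Ox→LC curve contributes ~53.9 pA at the 0.56 nM
  baseline; the 5-HT curve's upper bound is solved (−55.4 pA) so the
  balance yields 2.15 Hz, with the basal point near saturation
  (shift −8.3, slope 0.35 on the fM scale) so the serotonergic influence
  on the LC stays minimal — a few percent — under reuptake inhibition.
* **DRN.** The Ox curve's bounds are assumed 0→12 pA on the published
  shift/slope (basal Ox sits near its top); the NE curve's upper bound is
  solved (24.6 pA) with the 2.95 µM baseline at the curve midpoint
  (slope 0.5), which makes the DRN maximally sensitive to NE changes —
  the pathway through which reuptake inhibitors and the orexin antagonist
  reach the DRN in the drug simulations.

Every parameter carries a provenance tag: `reported` (published value
verbatim), `assumed` (shape choice), `anchored` (solved from a basal
current balance), `calibrated` (release parameter, below). Regenerated
values are constructions consistent with the published constraints, not
recoveries of unpublished fits.

**Release calibration.** The published per-stimulus release values do not
reproduce the published basal concentrations in closed form (e.g. 12.14 nM
per stimulus at 0.8 Hz gives a 0.92 nM 5-HT steady state at the LHA, not
1.6 nM), consistent with their published description as tuned quantities;
they are treated as seeds. `calibrate_release` solves each free parameter
in closed form from the steady-state relation
(`y_p = V_max·c*/((K_m+c*)·f)`, `α = η·c*/f`) using the current estimate of
the source rates, recomputes the coupled steady state, and iterates until
every target is within 1% (max 50 iterations), ending with a verification
simulation. Because the anchored curves make the basal state an exact
current-balance fixed point, the procedure converges in one parameter
update; both seed and calibrated values are retained. The calibrated
fixed point is reached from a cold start as well (two-start agreement is
tested to 1e-3 relative).

## Drug model

Reuptake inhibitors multiply K_m at every site of their species (V_max
unchanged; 5× for the fluoxetine-like SSRI preset, 3×/5× NRI presets).
The competitive-antagonist operator adds to a curve's shift (ED₅₀
multiplies by 10^Δ, supremum untouched); the irreversible operator
compresses `p_UR` towards `p_LR` (range shrinks, ED₅₀ location untouched).
The bundled SB-334867-A preset instead installs its published parameter
replacements verbatim (LC: 3.8→2 pA, 54→51 pA, −2.3→−4.192, 0.341→0.592;
DRN: −2.08→−2.97, 0.452→0.367), because the measured effect changes all
four parameters rather than a pure lateral shift; note the published shift
change moves *left* in this convention although the drug is described as a
rightward-shifting competitive antagonist — the values are stored as
printed, not reinterpreted. Combinations apply sequentially and are
order-independent when the drugs touch disjoint parameters (asserted for
the bundled triple). All transformations are pure: the input spec is never
mutated.

## Synthetic dose–response generator

Emulates a pharmacology concentration–response experiment: log-spaced
concentrations spanning ±2 decades around the curve midpoint (≥3 decades
enforced), sigmoid response plus i.i.d. Gaussian noise, seeded and
bit-reproducible. Defaults — 8 points per replicate, 2%-of-range noise —
mirror the small digitised response tables such curves are fitted to. What
it does *not* emulate: heteroscedastic assay noise, concentration
uncertainty, between-preparation variability, or non-sigmoid (biphasic)
responses; recovery results therefore bound estimator behaviour under the
stated noise model only.

**Recovery precision.** For a four-parameter logistic fitted to n points
at noise sd = 2% of the response range, the asymptote standard errors are
≈ sd/√(n/4); a "within 5% of truth" recovery bound is therefore only
meaningful for asymptotes whose magnitude is commensurate with the range
(5% of an asymptote that is ~8% of the range is a sub-sigma band no
estimator meets reliably). The noisy recovery tests use a benchmark truth
with 20→60 pA asymptotes on the published shift/slope; the slope's 5% band
is ~2 standard errors at n = 50, so that check is tied to the generator's
fixed default seed.

## Known limitations

* Acute drug actions only; no pharmacokinetics, no chronic receptor-density
  adaptation.
* The regenerated curve shapes are constrained, not identified: other
  (shift, slope, saturation) triples satisfying the same basal balances
  would change drug dose–response magnitudes (not the tested directions).
* Forward Euler only; stiff parameter regimes (reuptake rates approaching
  2/dt) require reducing dt manually.
* The threshold-linear f–I map has a hard kink; fits and simulations near
  threshold inherit its non-smoothness.
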