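# Methods

## Models

Four feedback architectures are built from the same four rate-law
primitives (all concentrations in nM, time in h):

* transcription: Hill-repressed, `S·K^h/(K^h + R^h)` with repressor R and
  cooperativity h = 4 (fixed, never searched), or constitutive `S` for the
  open Y loop of the semi-dual model;
* translation: first-order, `S·[mRNA]`;
* complex formation: mass action, `A·[X][Y] − B·[X:Y]`;
* nuclear transport: Michaelis–Menten in and out, `T₁·[C]/(T₂+[C])` and
  `U₁·[N]/(U₂+[N])`;
* degradation: Michaelis–Menten plus first-order,
  `D·[s]/(L+[s]) + d·[s]`.

The saturable degradation is what lets a short loop oscillate at h = 4;
with purely linear degradation a three-variable loop would need much
higher cooperativity.

State orders and wiring:

* **single** (m = 3): mRNA(X) → X → X(nuc); X(nuc) represses
  transcription; output X(nuc).
* **semi-dual / dual** (m = 6): mRNA(X), X, mRNA(Y), Y, X:Y, X:Y(nuc).
  X and Y associate in the cytoplasm; only the complex shuttles into the
  nucleus, where it represses *X* (semi-dual) or both *X* and *Y* (dual —
  the two models differ only in the Y-mRNA equation). Output X:Y(nuc).
* **redundant** (m = 6): two fully independent copies of the single loop;
  the only coupling is the readout X(nuc) + Y(nuc).

Parameter families (canonical order: X-loop first, then Y-loop, so the
symmetry constraint is an index renaming): S = transcription maximum
rates and translation rate constants (S1/S2 for the X gene, S3/S4 for Y),
K = transcription affinities, A/B = association/dissociation, T/U =
import/export (odd = maximum rate, even = affinity), D1..Dm = maximum
Michaelis–Menten degradation rates per species in state order,
D(m+1)..D(2m) = first-order degradation rate constants, L = degradation
affinities. Reference values: every rate and affinity 1.0 in its unit;
first-order degradation constants 0.01 h⁻¹; h = 4.

**Kinetic symmetry.** For the dual and redundant models the search range
of each Y-loop parameter is `[x/(1+ρ), x·(1+ρ)] ∩ global bounds`, where x
is the sampled X-loop counterpart. This multiplicative band is the
minimal family with the three required limits — it collapses to {x} at
ρ = 0, widens monotonically with ρ, and covers the full global range at
ρ ≥ 99 — and is symmetric in log space, matching the log-uniform prior.

## Simulation and feature extraction

LSODA (via `scipy.integrate.odeint`) with rtol 1e-7, atol 1e-9 nM on a
0.25 h output grid; the Hill exponent and Michaelis terms make the
systems moderately stiff. Default run: 1000 h from 0.1 nM in every
species, first 500 h discarded, leaving ≥ 20 circadian cycles of
attractor. Integration failure and non-finite states are mapped to a
"not oscillatory" result so parameter searches continue.

Peaks and troughs of the output are located with
`scipy.signal.find_peaks` (absolute prominence 1e-3 nM to ignore
numerical ripple) and refined by three-point parabolic interpolation, so
period and amplitude do not inherit the grid resolution. Period = mean
peak-to-peak interval; amplitude = refined global max − min over the
post-transient window (peak-to-trough — the 2–6 nM target window refers
to the full excursion); per-cycle amplitudes (peak minus following
trough) give the amplitude CV. *Sustained* requires ≥ 10 peaks, period
CV < 1% and amplitude CV < 10% — deliberately the same constancy
thresholds used for entrainment classification.

Loop balance: γ = mean[X(nuc)] / (mean[X(nuc)] + mean[Y(nuc)]), defined
for the redundant model; undefined (reported absent) if both means are
zero.

## Two-phase search

Genomes are log₁₀ multipliers of the reference values in [−1, 1]
(0.1–10 fold). Phase 1 samples `random_phase_trials` genomes log-uniformly
(Y-loop genes uniformly inside their ρ band) and keeps the
`population_size` best by fitness. Phase 2 is a generational GA:
tournament selection (size 2), BLX-α crossover (α = 0.5, rate 0.9),
per-gene Gaussian mutation (rate 0.1, σ = 0.1 log units), elitism 1,
children clipped back into bounds and the ρ band. Every individual that
reaches fitness zero is archived unless it duplicates an archived
solution (max |Δlog₁₀| < 0.01 across parameters); the search stops at
`n_solutions` or `max_generations` (a partial archive raises a warning,
never truncates silently).

Fitness is 0 exactly when the oscillation is sustained with period in
[23, 25] h and amplitude in [2, 6] nM (and, for semi-dual strata, mean
total Y — free Y plus cytoplasmic and nuclear complex — inside its
stratum); otherwise the relative distances of period/amplitude to their
windows (plus a log₁₀ distance for the stratum) are summed, and
non-oscillatory candidates sit on a constant maximal tier. The graded
interior steers the GA; the maximal tier keeps damped candidates from
masquerading as near-misses.

Determinism: one global seed is split with
`numpy.random.SeedSequence.spawn` into independent child streams for the
random phase and the GA, so each phase is independently reproducible.

## QMPS

Forward one-sided differences at Δ = 0.001, matching the definition of
the perturbation pᵢ(1+Δ); central differences would change the estimator
and are not used. Period and amplitude sensitivities share the same n+1
integrations. Perturbed (and baseline) evaluations restart from the
unperturbed post-transient state and integrate 400 h (first 100 h
discarded, ≈ 12 cycles with peak-count floor 6 under the same CV
thresholds): restarting on the attractor cuts the transient cost, and
evaluating the baseline under the identical protocol cancels any
protocol bias in the difference. If any perturbation loses the sustained
oscillation, the parameter set's QMPS is undefined: it is excluded and
counted, never imputed. Cumulative frequency is the empirical
step-function CF(x) = #(QMPS ≤ x)/n over defined values (the CF is taken
over QMPS itself, i.e. over the square sums); the median is the smallest
value with CF ≥ 0.5.

## Entrainment

Light modulation is multiplicative: during the light half of the LD
cycle the maximum degradation rate of clock protein X (D2) — and, in the
semi-dual and dual models, of the cytoplasmic X:Y complex (D5) — is
multiplied by δ; the neutral point is named `NEUTRAL_LIGHT_FACTOR = 1`.
The redundant model's Y loop is never light-perturbed. The square wave
(lights-on at t = 0, equal phases) is integrated phase-by-phase with
restarts at every switch, so the solver never steps over a
discontinuity. Forced runs last 80 forcing cycles with the first 40
discarded (entrainment transients are long near tongue edges); both are
configurable. En(p, ζ, δ) = 1 iff the forced cycles are constant (period
deviation < 1%, amplitude < 10%), the mean period equals ζ within 1%,
and the forced amplitude exceeds 0.1 nM — the floor (20× below the
fitness window's lower edge) excludes the small periodic ripple that any
quenched, non-oscillatory system exhibits when its degradation rate is
driven, which would otherwise register as a formally period-locked
response. The map probability is the exact fraction Σ En / N.
Classification is phase-invariant, so the lights-on-at-0 convention is
benign.

## Problem sizes

The package defaults are desk-scale: archives of 100 solutions
(`n_solutions`), 5000 random-phase trials, population 100, 200
generations. The test suite and the acceptance script run a reduced
replication chosen to keep a full comparison on one CPU in minutes:
15 solutions per study condition (20 for the acceptance script's single
model run), 250 random-phase trials (2000 for the weakly asymmetric
redundant conditions ρ = 0.1 and ρ = 0.01, whose oscillators are rare by
the interference mechanism the comparison itself demonstrates),
population 40, ≤ 80–120 generations, entrainment maps of 8 sets on a
9×7 (ζ, δ) grid. Median orderings across conditions are stable at these
sizes with the fixed seed; the absolute medians carry sampling noise
that the full-scale defaults would reduce.

## What the tests do and do not show

All inputs are generated by the package itself (there is no external
data); the replications therefore probe the *models'* comparative
robustness and entrainability, not any property of measured clock
kinetics. The search samples a bounded 0.1–10 fold box in log space, so
"all plausible parameter sets" means all within that prior; archives are
samples of the viable region, not exhaustive enumerations. Oscillation
classification is purely signal-based (no Floquet/bifurcation analysis),
and the non-entrained regime is not subdivided into quasiperiodic vs
chaotic.

## Known limitations

* Period/amplitude extraction needs ≥ 10 peaks; oscillators slower than
  ~50 h in the default window are classified unsustained by design.
* The γ statistic is implemented for the redundant architecture (nuclear
  X vs nuclear Y); the dual model's loops share one nuclear species, so
  no analogous per-loop nuclear readout exists there.
* QMPS assumes the target is differentiable along each parameter at the
  solution; near grazing bifurcations the finite difference can be
  large but is reported as computed (the Δ-consistency check at
  Δ ∈ [0.001, 0.01] guards the interpretation).
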