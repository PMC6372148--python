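# Methods

## Models

Four signaling-hub motifs are defined declaratively in
`src/hubsens/data/models/*.yaml` (schema documented there), all sharing an
activation reaction A in which the exogenous input signal s(t) drives the
conversion of inactive X into active Xa (written X\* in this field's figure
conventions), Michaelis–Menten in X:

* **M1, reversible reaction** — A plus first-order deactivation D.
* **M2, cycle** — deactivation D sends Xa to a refractory state Y which the
  cycle reaction R (Michaelis–Menten) recycles back to X; X+Xa+Y conserved.
* **M3, negative feedback loop** — Xa activates an inhibitor (FBA,
  Michaelis–Menten in Y with Xa as the catalytic modifier); active inhibitor
  Ya mediates the deactivation D (mass action in Xa·Ya); Ya reverts
  first-order (FBR).
* **M4, incoherent feedforward loop** — the signal also activates the
  inhibitor directly (FFA); Ya catalyses the additional deactivation DS
  (Michaelis–Menten in Xa); basal D and inhibitor reversion FFR are first
  order.

Each rate constant (k1, k2a, k2b, k3, k4) belongs to exactly one reaction, so
sensitivities can be reported under the reaction labels A, D, DS, R, FBA,
FBR, FFA, FFR.  Michaelis constants (km1, km2, km3) are estimated but not
perturbed by default (`include_km=True` adds them).

**Provenance of the numbers.** The published figure defining the motif
family's exact rate laws and original parameter values was not transcribable
from the material available to this project, so the model definitions are
*reconstructions*: the reaction sets, rate-law mix and parameter names follow
every textual constraint of the motif family, and the reference values were
chosen once — before any ensemble statistics were computed — to satisfy
three requirements: (i) responsive dynamics on the 0–300 min horizon with
mid-range pool occupancy, (ii) the characteristic motif signatures (M2/M3
overshoot-and-adapt, M4 strong peak-then-decline), and (iii) every reference
value strictly inside the estimation box ln p ∈ [−15, 5].  Conserved pool
totals are 1000 (arbitrary molecule-count units), which with the CLE's
√(propensity) noise gives replicate spreads of ~3–5% of signal — the scale
of typical immunoblot replicates.  All times are minutes; no unit conversion
occurs anywhere.

The ten input patterns S1–S10 (`data/signals.yaml`) are pure functions of
time: saturating rise at rate kon (fast 0.5/min, slow 0.02/min) up to a
switch time, then exponential decay at koff (fast 0.2/min, slow 0.01/min, or
sustained), covering all fast/slow initiation-by-decay combinations with
short-pulse and late-switch variants.  The exact published signal equations
were likewise not available; these forms reproduce the qualitative phase
combinations.

## Simulation

*Deterministic.* The conserved pools are eliminated by explicit substitution
(inactive = total − active), and the reduced ODE system is integrated by an
in-package adaptive Dormand–Prince RK45 kernel (numba-compiled) with forced
landing on the requested output grid; a scipy LSODA fallback handles stiff
parameter corners, and sets failing both are excluded from all downstream
statistics (the solver-error exclusion rule).  A full-state integration of
the unreduced system is kept as a test oracle and agrees to solver tolerance.

*Stochastic.* The chemical Langevin equation uses drift v·a(X) and diffusion
v·√a(X) per reaction (the √ follows the standard CLE; amounts are
interpreted as molecule counts, with a single configurable noise-scale
factor, default 1).  Euler–Maruyama steps of dt = 0.01 min (≪ the fastest
reference time scale of ~2 min) with independent N(0,1) increments per
reaction per step; negative excursions are clipped to zero and pool
overshoots rescaled before the next propensity evaluation.  Seeds: one root
seed per run; per-pattern child streams and per-replicate seeds are derived
with `numpy.random.SeedSequence.spawn`, so the full ensemble is reproducible
from the root seed alone.

*Control data.* 1000 replicates per pattern at the reference parameters in
the paper-scale profile; the quick profile (the default for tests and the
acceptance script) uses 100, which changes the SE band width but not the SD
band that classification uses.  Output X\* is sampled every 30 min over
(0, 300] — ten points; t = 0 is excluded since all patterns share the same
initial state.

## Fitness, scaling and classification

The cosine-error fitness sums 1 − cos² between the simulated and control
10-point output vectors over the ten patterns; it is invariant to positive
rescaling, matching dynamic *behavior* rather than absolute amplitude.  The
amplitude is restored by the per-pattern scaling factor α = |x̂_ctrl|/|x_sim|
(a single global α is available by option).  A set is **positive** iff the
α-scaled output lies within mean ± SD at all 100 grid points.

Two classification choices deserve justification:

* **SD, not SE, as the default band.**  With 1000 replicates the SE band is
  ~32× narrower than the replicate spread; numerically even the generating
  parameter set fails it somewhere on the 100-point grid (the acceptance
  suite demonstrates exactly this), so a nonempty positive class forces the
  SD reading.  `band="se"` remains available.
* **Detection floor.**  The band test adds 10⁻⁴ of the pattern's peak mean
  to each band.  On decay tails the molecule count reaches ~10⁻²–10⁻¹⁷ and
  every zero-clipped stochastic replicate sits at exactly 0 (SD = 0); a
  continuous trajectory can never hit 0 exactly, and points four orders of
  magnitude below the signal carry no information about reproducibility.

## Parameter estimation

Coordinates are natural logarithms in the box [−15, 5] (values
[e⁻¹⁵, e⁵] ≈ [3·10⁻⁷, 148]); a log10 reading of the same bounds is a config
switch.  The search is a memetic genetic local search: a generational GA
(population 16 per parameter dimension, 60 generations, tournament selection
k = 3, uniform crossover, Gaussian mutation σ = 0.8, elitism) with a
Lamarckian step every 10 generations that Nelder–Mead-polishes the current
best individual and re-injects it.  After the GA, adaptive-simplex polishing
runs from the distinct archive elites and from fresh random multi-start
seeds, and both extra restarts and full GA retries (with derived seeds)
continue until the best cosine fitness reaches the goal of 6·10⁻³ or the
budgets (20 restarts, 3 retries) are exhausted — the goal sits an order of
magnitude below the ~10⁻¹–10⁻² level of the landscape's degenerate basins
(e.g. M1 has a prominent basin where activation is effectively
zeroth-order), and a converged population alone would polish a single basin.
An intensification round perturbs the best basins (σ = 0.3) and re-polishes.
Final candidates are the best archive points passing a greedy
minimum-distance filter (radius 0.05 in log space), so returned sets are
distinct.  During the search, integrations are capped at 4000 accepted steps
per pattern (~40× the need of the reference basins) and failures score
worst-case fitness N = 10; final candidates are re-evaluated with the
production solver (with stiff fallback) at classification time.  All budgets
are config-exposed; the defaults were sized for a desk-scale machine and
deliver ~100 positive sets per model in the quick profile.

## Sensitivity analysis

The target is q = ∫₀³⁰⁰ X\*(t) dt, computed by composite trapezoid on a
0.5-min grid (601 points, well below the 30-min sampling grid).  The
log-sensitivity to each reaction's rate constant uses the one-sided forward
difference with a 0.1% increase, s = (q⁺/q − 1)/0.001.  The perturbed
integration *replays the exact accepted-step sequence* of the base run, so
truncation and quadrature error are shared and cancel to first order; for a
model whose output is proportional to the perturbed constant the computed s
equals 1 to rounding error, and the test suite holds the forward difference
within 5% of a central-difference oracle.  Because s is a ratio of integrals
of one trajectory, the α scale cannot affect it; stored q values are
unscaled.

## Trend statistics

* PCA standardises columns by default (sensitivity magnitudes span orders of
  magnitude across reactions); component signs are fixed by making the
  largest-magnitude loading positive.
* z-scores across reactions use the sample SD (ddof = 1; population SD by
  switch), so a two-reaction model yields ±0.707 exactly.
* Dominance percentages count strict inequalities with ties defined by a
  1e−9 relative tolerance (structurally identical reactions tie exactly);
  the greater/less/equal triple sums to exactly 100 per cell.  Both the
  signed comparison and the |s| ("strength") comparison are computed; the
  analysis outputs report both, since sign-split pairs (activation vs
  deactivation) dominate trivially in the signed reading.
* Pearson correlations between q and s are reported per (pattern, reaction)
  over positive sets; cells with <3 sets or zero variance are missing.

## What the synthetic conditions do and do not show

The control data emulate replicate ensembles of a *known* generating model —
including multiplicative-style CLE noise, replicate summaries, and arbitrary
amplitude units — but not features of real biological data: no measurement
background, no systematic (batch) error, no model mismatch between the
data-generating process and the fitted model, and noise whose size is set by
the chosen pool totals rather than by an assay.  Passing tests therefore
demonstrate that the *pipeline* recovers structure-imposed sensitivity
trends under its own generative assumptions, not that any particular
biological hub has those trends.

## Numerical choices and limitations

* RK45: scaled-RMS error control with a PI step controller; non-finite
  error estimates hard-reject the step.  Tolerances by stage: sensitivity
  runs at rtol/atol 10⁻⁸ (the 0.1% perturbation signal must be resolved),
  search and classification at 10⁻⁵/10⁻⁴ (the band is ~3% of signal), with
  step budgets of 2·10⁵ / 4·10³ / 8·10³ respectively; the LSODA fallback is
  capped at 10⁴ internal steps so pathological sets fail fast and are
  excluded.
* The goal-driven restart logic stops adding local searches and GA retries
  once the best cosine fitness reaches 6·10⁻³ — well below the ~10⁻²
  level of the degenerate basins and well inside the band-passing regime.
* Quick-profile problem sizes — 100 replicates, 100 candidates, 1000 random
  sets, ≤40 positive sets in the per-model sensitivity tables, 1000-replicate
  dt = 0.05 ensembles for the SE-band demonstration — are the package's
  desk-scale defaults; the `paper` profile scales to 1000/1000/10000.
* The genetic search is a generic stand-in for the asynchronous
  genetic-local-search family; only its contract (diverse, low-fitness
  candidates) is honoured.  Success rates on M3/M4 depend on the restart
  budget; an unlucky seed can return fewer positives.
* Random-sampling positives are astronomically rare in ≥6 dimensions; the
  positive class is in practice populated by the estimator, as intended.
* Exact-SSA simulation, τ-leaping, global sensitivity measures and
  hypothesis tests on dominance percentages are out of scope.
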