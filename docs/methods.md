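# Methods

This note documents the models, estimators and numerical choices behind
`odehybrid`, in the spirit of a solver manual: what is computed, under which
assumptions, with which defaults, and where the design was genuinely open.

## Flux-derived stochastic interpretation of an ODE model

The package treats a user-supplied ODE model — species list, parameters,
drift evaluator f(x, t), initial state — as the definition of a piecewise-
deterministic Markov process. Each species i carries a birth channel
(+1, propensity a⁺ᵢ = f⁺ᵢ(x, t)) and a death channel (−1, a⁻ᵢ = f⁻ᵢ(x, t)),
where f = f⁺ − f⁻ is a production/degradation split of the drift. This
"minimal reaction set" is exact for birth–death-type kinetics and is the
natural stochastic reading of models written with effective rate laws,
where no mechanistic reaction network exists.

**Automatic decomposition (zero-clamp rule).** When the user supplies no
split, production is the drift with the focal species clamped to zero,
floored at 0, and degradation is the non-negative remainder:

    f⁺ᵢ(x, t)  = max( fᵢ(x with xᵢ := 0, t), 0 )
    f⁻ᵢ(x, t) = max( f⁺ᵢ(x, t) − fᵢ(x, t), 0 )

Rationale: degradation terms typically vanish at zero copy number, so
clamping isolates the production terms without symbolic algebra. The split
is exact for linear mass-action kinetics with non-negative production
constants and for Hill-type production with linear decay; it *fails* for
autocatalytic drifts (production proportional to the focal species). The
identity f⁺ − f⁻ = f is therefore probed numerically (initial state plus 32
states obtained by scaling the initial state componentwise with
Uniform(0.1, 10) draws, seed 1234); on failure a warning is emitted, the
decomposition is flagged inconsistent, and stochastic simulation refuses to
proceed without an explicit user split. A drift that is undefined
(non-finite) with a species clamped to zero is reported as an error naming
the species. How constant sinks that do not vanish at zero copy number
should be treated is genuinely open; we clip the death propensity at zero
(and clamp counts at zero on firing), accepting a small boundary bias in
exchange for guaranteed non-negativity.

**Units.** Stochastic propensities are copy-number fluxes, so all
stochastic work happens in molecule counts. Concentration models are
converted per species via Ω = N_A·V·u (N_A = 6.02214076×10²³ mol⁻¹, V the
species' compartment volume in litres, u the molar-unit factor from the
enumerated set M/mM/µM/nM): state n = Ω∘x, drift dn/dt = Ω∘f(n/Ω, t),
decomposition transformed identically. Time units are untouched.

## Hybrid engine

Given a partition (stochastic set S, deterministic set D) the engine loops:

1. evaluate all a⁺ᵢ, a⁻ᵢ (i ∈ S) at the current hybrid state and local
   time; clip negative values to zero (counted; a warning fires if clips
   exceed 0.1% of evaluations); a₀ = Σ;
2. draw τ ~ Exp(a₀) (∞ if a₀ = 0);
3. advance the D-coordinates over h = min(τ, Δt, gap to the next input
   event time, T − t) with LSODA at (rtol, atol), S frozen;
4. if the jump fired first, select one channel by cumulative-sum inversion
   over channels in species order, birth before death, and apply ±1 with
   clamping at zero;
5. record on the output grid — D by the integrator's dense values at grid
   times, counts as right-continuous step functions.

Propensities are *frozen* between re-evaluations rather than integrated;
the synchronization interval Δt (default 0.1 benchmark time units, always
user-settable) caps how stale they can become, trading accuracy against
cost. The exact integrated-hazard alternative is available as the
Haseltine–Rawlings reference solver, so the approximation is directly
testable. The partition is computed once at initialization and stays fixed
for the whole run; online reclassification is out of scope.

Determinism: one `numpy` Generator per run; the event-time draw and the
channel draw consume the stream in fixed order, so a (system, T, seed,
grid) tuple reproduces bitwise. Ensembles seed replicate r with
base_seed + r, making results independent of execution order. Fractional
initial values of stochastic species are rounded half-up (2.5 → 3); the
original convention for this is unspecified, so the package fixes one.

## Reference solvers

* **Exact SSA** — Gillespie direct method on the derived network: exact
  event times, counts recorded as right-continuous steps. Zero total
  propensity freezes the state (not an error). Propensities with explicit
  time dependence are evaluated at event times and held between events.
* **Tau-leaping** — fixed leap τ, Poisson channel counts with frozen
  propensities; a step that would drive any count negative is retried at
  half the leap (up to 20 halvings), then falls back to exact single-event
  SSA for that sub-interval. Exact for constant propensities.
* **Haseltine–Rawlings hybrid** — channels are partitioned into a fast
  subset forming a deterministic drift Σ_fast ν_j a_j (ODE, not Langevin —
  a deliberate variant choice matching the usage context) and a slow subset
  fired exactly: the state is augmented with dg/dt = Σ_slow a_j, a jump
  fires when g reaches −ln U (located by the ODE solver's event
  root-finding), the channel is chosen ∝ propensity *at the located firing
  time*, and g resets. With all channels slow this is distributionally
  exact; with all channels fast it reduces to the ODE. On the benchmark the
  partition "channels touching stochastic-labeled species are slow"
  reproduces the published statistics; the original configuration is not
  described, so this mapping is an interpretation.
* **ODE** — LSODA (or BDF) with dense output on the grid; for a network,
  the macroscopic rate equation Σ_j ν_j a_j.

## Pre-simulation features and labeling

The deterministic pre-simulation integrates the model on a uniform grid
(defaults: horizon 500 time units, 2001 points, rtol 1e−6, atol 1e−9).
The horizon comfortably equilibrates every bundled model family (slowest
relaxation times are tens of time units); stiff or ultrasensitive systems
may need longer, which is why it is a per-call setting rather than inferred.

Each species' series is summarised into 18 features covering amplitude
(mean, min, max, range, quantiles q05/q50/q80/q99, log10(1+·) transforms of
mean/q80/q99), variability (population SD, CV, a Fano-style sd²/(mean+ε)
ratio with ε = 1e−9), and temporal behaviour (count of strict sign changes
of first differences, lag-1 autocorrelation of the mean-removed series — 0
for constant series, final value over max, fraction of time at or above
half-max). Quantiles use linear interpolation of order statistics (type 7)
so labels are reproducible across implementations. The exact feature list
is this package's own; it deliberately includes the two label-defining
quantiles so the forest can in principle recover the labeling rule.

**Labeling rule.** A species is *stochastic* (1) iff q₀.₈₀ < 200 and
q₀.₉₉ < 200 molecules, strict inequalities. The rule is conservative —
a transient burst keeps a low-mean species in the deterministic class via
its q99 — which is exactly where abundance-only heuristics (mean or median
below 200) misclassify.

## Classifier, calibration, evaluation

The partitioner is a random forest: 300 trees, unlimited depth, √F features
per split, balanced class weights, fixed seed — robust defaults, all
configurable; the decision threshold is fixed at 0.5, with ties going
stochastic (erring toward the higher-fidelity regime). Raw forest
probabilities are remapped by isotonic regression (monotone non-decreasing,
clipped to [0, 1]) fitted on leave-one-model-out fold predictions: each
fold holds out *all* species of one model, so calibration and evaluation
both measure generalization to unseen systems, not unseen species.

Evaluation uses the same LOMO protocol. Per fold: balanced accuracy
(TPR+TNR)/2 and the Matthews correlation coefficient from the fold's
confusion matrix. Folds whose ground truth is single-class contribute the
recall of the present class as their balanced accuracy and are excluded
(flagged) from the mean MCC; folds with two-class truth but degenerate
predictions score MCC 0 by the usual convention. Because whether published
summaries pool folds or average per-fold metrics is ambiguous, the report
carries both (per-fold means and pooled-confusion metrics). Nested
calibration inside the evaluation (each outer fold re-runs inner LOMO
calibration over the remaining models) is quadratic in the number of
models; the inner calibration forests default to 100 trees — forest
probabilities are stable well below 300 trees at 18 features, and the
outer per-fold predictor keeps the full 300 — which keeps a 40-model
evaluation around four minutes on one CPU.

Abundance heuristics (stochastic iff trajectory mean, or median, < 200) are
evaluated on the identical folds and metrics for comparability. Threshold
sensitivity relabels all species with the rule at τ ∈ [150, 300] and
reports the fraction whose label differs from the τ = 200 baseline; raising
τ can only move labels 0 → 1, a monotonicity the tests assert.

## Synthetic training corpus

No external dataset is used: `generate_corpus` produces a deterministic,
seeded corpus of validated count-unit ODE models emulating a training set
that spans deterministic, stochastic-like and multiscale regimes. Five
families are mixed (weights 1:2:1:1:1):

* **birth_death_chain** (2–6 species) — linear synthesis/decay chains;
* **expression_cascade** (3–6 gene pairs, i.e. 6–12 species) — mRNA tiers
  drawn from the low-copy range, protein tiers from the high-abundance
  range, genes coupled by linear activation; double weight because it is
  the family that mixes both tiers within one model;
* **repressilator_variant** (6 species) — the symmetric oscillator with
  randomized amplitude, Hill coefficient and protein kinetics, scaled into
  the low-copy regime (noisy circuit mRNAs);
* **michaelis_menten_module** (3–5 species) — a large substrate bolus
  consumed by saturable kinetics feeding a product chain: the transient
  burst makes mean/median poor predictors of the upper quantiles, the
  regime where heuristics provably err;
* **autoregulation** (2 species) — negative feedback with a low-copy mRNA
  and an abundant protein.

Rate constants are sampled log-uniformly so each species' deterministic
stationary scale lands near a target drawn from the low-copy range
([1, 120] molecules) or the high-abundance range ([400, 10⁶]), mirroring
the mRNA/protein copy-number gap. The gap leaves the 150–300 band swept by
the threshold-sensitivity analysis essentially unpopulated (the tests
assert ≥ 90% of stationary values fall outside it), which is what makes
the flip fraction small; a corpus with substantial mass near 200 molecules
would show larger flips, so the sensitivity result is a statement about
this abundance distribution, not a universal constant. The default corpus
is 40 models (~210–270 species, both regimes populated at every tested
seed); the per-model random stream is seeded from (corpus seed, model
index), so a spec + seed pair regenerates the corpus bitwise.

What the generator does *not* emulate: experimentally calibrated rate
constants, conservation laws and moiety cycles, widely separated stiff
timescales within one model, or non-Markovian effects (delays, cell
division). Passing classifier tests therefore demonstrate that the pipeline
recovers regime structure of this corpus's kind — clean scale separation
with burst confounders — not performance on arbitrary real models.

## Benchmark protocol and estimators

The two-stage gene-expression benchmark (k₁ = 5, d₁ = 1, k₂ = 50,
d₂ = 0.1, counts, started at (0, 0)) was chosen because its stationary
moments are closed-form: M is immigration–death, stationarily Poisson(5);
Var(P) = P*(1 + k₂/(d₁+d₂)) = 116 136 with P* = 2500. The rate values
themselves are a package choice made to land the steady state exactly on
(5, 2500) at round numbers; only the stationary statistics are pinned by
the published description.

Stationary statistics pool all grid samples with t ≥ burn-in across
replicates (ergodic averaging — cheaper than end-point ensembles at equal
accuracy for these ergodic systems; both modes exist) and report the mean
and population variance (denominator n). The default protocol is T = 5000,
output grid step 0.1, burn-in 50, single replicate for SSA/tau-leap/HR,
Δt = 0.1 for the hybrid engine. The cross-method relative error is
ε = (1/S)·Σᵢ |meanᵢ − refᵢ|/|refᵢ| against the deterministic steady state.
The ODE row reports the steady state at T with variance exactly 0: a
deterministic trajectory has no run-to-run variability, and a time-window
variance over its transient would be spuriously positive.

Caveat on single-run estimates: time samples are autocorrelated (protein
correlation time ≈ 1/d₂ = 10), so the effective sample size of a T = 5000
window is a few hundred for P, giving the single-run Var(P) estimate a
relative SD near 10%, and the T = 2000 tau-leap relative error a typical
magnitude of order 0.01. Quantities at that resolution fluctuate seed to
seed; they are unbiased, and longer horizons or replicate ensembles shrink
them as 1/√T.

## Numerical choices and edge cases

* Stiff integration everywhere via LSODA (BDF accepted in the
  ODE/pre-simulation entry points); default rtol 1e−6, atol 1e−9.
* Output grids are uniform [0, T]; counts are recorded right-continuously,
  deterministic coordinates by dense interpolation.
* Channel order (species order, birth before death) and the
  cumulative-sum inversion are fixed for reproducibility.
* a₀ = 0 freezes the stochastic clock until the next input event or T.
* Input signals declare their discontinuity times; simulators never step
  across one, and propensities/drifts are evaluated at local simulation
  time (non-autonomous models).
* Validation never crashes on a misbehaving drift: evaluator exceptions,
  length mismatches, non-finite values and decomposition violations become
  human-readable diagnostics on the fixed probe set.

## Known limitations

* Only ±1 birth/death channels are derived from a drift; multi-molecule
  stoichiometries require an explicit `ReactionNetwork`.
* The frozen-propensity hybrid is biased for species whose propensities
  depend strongly on fast deterministic coordinates when Δt is large;
  choose Δt below the fastest coupled timescale, or use the
  Haseltine–Rawlings solver.
* Autocatalytic and non-vanishing-sink drifts need user decompositions.
* No SBML import/export; declarative files cover registered families and
  plugin hooks only. No dynamic repartitioning mid-run; no delays or
  division events.
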