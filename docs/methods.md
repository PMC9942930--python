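# Methods

## Model and assumptions

`fluctest` analyzes a two-state Markov switching model embedded in an
exponentially growing clone:

* every cell divides at rate `kx`, independent of its state (state-dependent
  proliferation, cell death, and density-dependent rates are out of scope);
* every cell switches State 1 → State 2 at rate `k1` and State 2 → State 1 at
  rate `k2`, constant in time, identical across colonies, memoryless, and
  unaffected by divisions; residence times in each state are therefore
  exponential with means `1/k2` (State 2) and `1/k1` (State 1);
* both daughters inherit the mother's state at division — heritability of
  the state is the premise of the fluctuation test;
* the founder cell of each colony is drawn from the stationary bulk:
  State 2 with probability `f = k1/(k1+k2)`.

Time is measured in units of `1/kx` by convention (`kx = 1`), so `t` is the
average number of generations of expansion and `Z = kx/(k1+k2)` compares the
switching relaxation time to the cell cycle. The transient heritability of
State 2 — the quantity the method exists to estimate — is `kx/k2`
generations.

## The three CV² predictors and their validity regimes

With Bernoulli founder states, the fraction process starts with
`CV_f²(0) = (1−f)/f` and relaxes as colonies equilibrate. The three
predictors differ in how much demographic stochasticity they keep:

1. **Deterministic** (`cv2_deterministic`): conditioned on the founder
   state, growth and switching follow ODEs; `CV_f² = ((1−f)/f) e^(−2(k1+k2)t)`.
   Only `f` and `k1+k2` enter (`kx` cancels). Because it ignores the
   stochastic timing of early divisions and switches, it systematically
   *underestimates* the fluctuations of the full stochastic process — the
   formula-comparison benchmark asserts this ordering.
2. **Independent closure** (`cv2_independent_approx`): uses exact moments of
   the stochastic counts plus the closure `⟨f²x²⟩ ≈ ⟨f²⟩⟨x²⟩`. Most accurate
   at early-to-middle times when fluctuations are large — the informative
   regime — and therefore the default inference formula.
3. **Small noise** (`cv2_small_noise_approx`): second-order Taylor expansion
   of `x₂/x` around mean counts. Accurate at late times when fluctuations
   are genuinely small; at early times the expansion is outside its domain
   of validity and *overshoots*: the curve leaves `(1−f)/f` with slope
   `+kx(1−f)/f`, peaks at `t* = ln((2+Z)/4) / (kx(1−2/Z))`, and only then
   decays. Its slow-switching limit is `(2−e^(−kx t))(1−f)/f` rather than
   the frozen-state value `(1−f)/f`. These are properties of the
   approximation, not defects of the implementation; the test suite asserts
   monotone decay in `t` for predictors 1–2 and the unimodal-then-decay
   shape plus the exact large-`Z` limit for predictor 3.

All three predictors are monotonically increasing in `Z` at fixed
`(f, kx, t)` — slower switching always means larger fluctuations — which is
what makes the inversion well posed.

### Numerical form

The two stochastic predictors share the kernel
`[2Z e^(kx t (Z−2)/Z) − (2+Z)]/(Z−2)`, which has a removable singularity at
`Z = 2` and cancels catastrophically near it. Both are evaluated as
`2Z·expm1(kx t (Z−2)/Z)/(Z−2) + 1`, which is exactly 1 at `t = 0` for every
`Z` and loses no precision near the branch; for `|Z−2| < 1e−8` the closed
limit `1 + 2 kx t` is substituted. Degenerate fractions (`f ∈ {0,1}`) raise
rather than returning 0/∞, because a silent infinity would corrupt any
downstream inference.

## Simulator

Since the switching process is a two-state Markov jump process independent
of division timing, the state of a cell any interval `dt` after birth has
the closed-form transition law

```
P(2 | start 2) = f + (1−f) e^(−(k1+k2) dt),   P(2 | start 1) = f (1 − e^(−(k1+k2) dt)).
```

The simulator therefore generates only the *division skeleton*: per cell it
draws the cycle time from the configured family and then draws the state at
division (or at the assay time) from this kernel; daughters are born with the
mother's division-time state. This is distributionally exact — identical in
law to scheduling every individual switch event — while letting whole
generation waves be drawn with vectorized numpy calls. An independent
aggregate-propensity (Gillespie) simulator over `(N1, N2)` is kept solely as
a cross-check; the test suite verifies that means and variances of
`(x, x₂)` from the two simulators agree within Monte-Carlo error.

Cell-cycle families: exponential (mean `1/kx`; the only family for which
mean colony size is exactly `e^(kx t)`), gamma, and lognormal, the latter two
parameterized by mean `1/kx` and a coefficient of variation (default 0.25, a
typical mammalian-cell dispersion; with non-exponential cycles the realized
Malthusian rate differs from `kx` by the Euler–Lotka correction). All
families draw cycle times i.i.d. per cell — multi-generational cell-cycle
memory is out of scope.

Reproducibility: a fluctuation test takes one master integer seed; colony
`i` runs on `SeedSequence((seed, i))`, so any single colony can be
re-simulated bitwise identically in isolation. A per-colony cap of 5·10⁶
cells guards memory with a clear error instead of silent truncation.

## Inference

* `f̂` = unweighted mean of colony fractions (each colony is one draw of the
  fraction process, regardless of its size); `⟨f(t)⟩ = f` at every `t` makes
  this unbiased.
* `CV_f²` uses the unbiased `(n−1)` sample variance — colony counts as small
  as 40 are typical.
* `Z` solves `predictor(Z) = CV_f² − CV_NC²`: closed form for the
  deterministic formula, otherwise Brent bisection in `log10 Z` over
  `[1e−6, 1e6]` (monotonicity guarantees a unique root; round trips are
  exact to better than 1e−6 relative).
* Identifiability flags instead of extrapolated numbers: each formula has an
  attainable range at fixed `(f, kx, t)` — deterministic `(0, (1−f)/f)`,
  independent `((1−f)/f/(2e^{kx t}−1), (1−f)/f)`, small-noise
  `(e^{−kx t}, 2−e^{−kx t})·(1−f)/f`. A corrected CV² at or below the floor
  raises `fast_switching_limit` (states effectively non-heritable; `Z` not
  identifiable); at or above the ceiling raises `slow_switching_bound` and
  reports the bracket top as a lower bound on `Z`. A mean fraction of
  exactly 0 or 1 raises `degenerate_fraction`.
* The noise-control correction `CV_NC²` is subtracted additively for every
  formula (the additive-independent-technical-noise argument does not depend
  on which predictor is used). Besides a measured control, the package can
  compute a *demographic* floor from the dataset itself,
  `(1−f̂)/f̂ · mean(1/Nᵢ)`: even non-heritable states produce this much CV²
  from within-colony binomial sampling, and for small or broadly-sized
  colonies it dominates. With this correction, fast-switching ground truths
  are correctly flagged as non-identifiable instead of yielding spurious
  residence times of ~2 generations.
* Intervals come from a percentile bootstrap over colonies (resampled with
  replacement, flagged resamples counted and reported, intervals declared
  unreliable when more than half the resamples are flagged). The bootstrap
  quantifies sampling variability only: on fully stochastic data the
  independent-closure inversion has a systematic upward bias (below), so
  intervals sit above the truth rather than covering it at nominal rate.
  Coverage is nominal when the generating model matches the inference
  formula, which the test suite demonstrates with the deterministic mixture.

## Benchmarks and chosen problem sizes

* Formula comparison: 200 colonies × 5 repeats over `t ∈ {1,…,5}`
  generations in the reference regime `f = 0.1`, `kx = 1`, `k2 = 1/5`
  (`k1 = 1/45`, `Z = 4.5`, true State-2 residence 5 generations). This keeps
  end-of-run colonies at ~`e⁵ ≈ 148` cells and preserves the statistical
  structure of the full 1,000 × 20 experiment at ~20× less cost; the full
  scale is available via `--full-scale`. Tabulated error bars are one
  standard deviation across repeats, on the CV (not CV²) scale.
* Recovery benchmark: 40-colony datasets (gamma or lognormal cycles),
  independent-closure inversion, 100 replicates; consistency is checked by
  RMSE decreasing at 200 and 1,000 colonies. The recovered median residence
  is ~7 generations for a 5-generation truth: the independent closure
  underestimates the true CV, so the inversion compensates with a larger
  `Z`. This bias is inherent to single-time-point formula matching and is
  reported, not corrected; likelihood-based fitting of the full fraction
  distribution would be the remedy and is out of scope.
* What the synthetic data do *not* emulate: measurement noise in state
  classification (beyond the additive CV_NC² model), cell death, state- or
  density-dependent rates, cell-cycle memory across generations, and
  finite-pipetting artifacts of real colony assays. Passing benchmarks shows
  the estimator works when the model class is right; it does not validate
  the model class against any particular biological system.

## Degenerate and edge inputs

`t = 0` returns the founder-only observation; `k1 = k2 = 0` makes `f`
undefined, so simulation then requires explicit founder states and inference
refuses; single-colony datasets are rejected wherever a variance is needed;
colony tables with `n_state2 > n_total`, non-integer counts, or duplicate
ids are rejected naming the offending row.
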