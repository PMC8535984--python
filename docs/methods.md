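# Methods

## Grey forecasting models

Grey models target short positive time series — a couple of decades of
annual counts or rates — where distribution-based methods have too little
data to work with. The raw series x⁽⁰⁾ = (x⁽⁰⁾(1), …, x⁽⁰⁾(n)) is first
smoothed by the accumulated generating operation (AGO)

    x⁽¹⁾(k) = Σᵢ₌₁..k x⁽⁰⁾(i),

and a first-order grey difference equation is fitted to the accumulated
level. Pairing each increment x⁽⁰⁾(k) with a *background value* z⁽¹⁾(k)
built from the adjacent accumulated levels gives, for k = 2..n,

    x⁽⁰⁾(k) + a·z⁽¹⁾(k) = rhs(k),

a system linear in the development coefficient `a` and the grey action
quantity `b`, solved by ordinary least squares, (a, b)ᵀ = (BᵀB)⁻¹BᵀY.
The continuous-time (whitened) counterpart of the difference equation then
yields a closed-form predictor for x⁽¹⁾, and first differences restore
fitted and forecast values on the original scale.

**GM(1,1)** (classical): z⁽¹⁾(k) = (x⁽¹⁾(k) + x⁽¹⁾(k−1))/2, rhs = b, and

    x̂⁽¹⁾(k) = (x⁽⁰⁾(1) − b/a)·e^(−a(k−1)) + b/a,

so fitted increments decay (or grow) geometrically with ratio e^(−a). This
suits monotone series.

**GGM(1,1)** (Gaussian grey): time enters through a Gaussian weight.
With location μ and width σ (the *standard* model fixes μ = 0, σ = 1),

    z⁽¹⁾(k) = ½·[ (k−μ)/σ² · x⁽¹⁾(k) + (k−1−μ)/σ² · x⁽¹⁾(k−1) ],
    rhs(k)  = b·(k − ½ − μ)/σ²,

and the whitened solution is the Gaussian exponential

    x̂⁽¹⁾(k) = (x⁽⁰⁾(1) − b/a)·e^(+a(1−μ)²/(2σ²))·e^(−a(k−μ)²/(2σ²)) + b/a.

For a > 0 and x⁽⁰⁾(1) < b/a this is an S-shaped saturating curve whose
increments rise to a single peak near k ≈ μ + σ/√a and then fall — the
shape of count series that climb for a few years and then decline.

### Anchoring

The first exponential factor is chosen with a *positive* exponent so the
two factors cancel at k = 1 and x̂⁽¹⁾(1) = x⁽⁰⁾(1) exactly — the standard
grey-model anchoring convention, and the only self-consistent reading of
the whitened solution's initial condition. The variant with both
exponents negative circulates in the literature; it is available behind
`predict_cumulative(..., anchored=False)` for comparison but is not used
by any default path.

### Admissibility and transforms

Before fitting, the order ratios λ(k) = x⁽⁰⁾(k−1)/x⁽⁰⁾(k) are screened
against the interval (e^(−2/(n+1)), e^(2/(n+1))). The check is
*advisory*: practice routinely fits grey models to mildly inadmissible
series, so violations produce a warning and a report rather than an
error (`strict=True` upgrades it to an error). For inadmissible data two
optional pre-fit transforms are provided, both off by default: a constant
shift x → x + c and a log transform, each inverted automatically on
fitted values and forecasts. Errors are always computed on the original
scale.

### Error conventions

Two relative-error conventions coexist in the grey literature. The API
default divides by the observed value, δₖ = (x̂⁽⁰⁾(k) − x⁽⁰⁾(k))/x⁽⁰⁾(k);
`error_denominator="fitted"` divides by the fitted value instead, which
is the convention under which published fit tables for this model family
reproduce exactly. Signed errors are reported as (fitted − observed)/denominator;
the summary statistics δ (mean absolute) and the maximum use magnitudes.

### Numerical choices

* Least squares via `numpy.linalg.lstsq` after an explicit rank check;
  a rank-deficient design raises rather than returning a pseudo-inverse fit.
* a = 0 makes b/a undefined and raises a degenerate-model error.
* All fitting is deterministic; identical inputs give bit-identical fits.
* Report rendering is pinned (predictions 3 decimals, errors and
  coefficients 6 decimals); internal comparisons always use full
  double precision.

### Known limitations

Both predictors are smooth two-parameter curves in k. They cannot follow
abrupt single-year breaks: the packaged accident-death series drops 35%
between 2015 and 2016, and no member of either family tracks that step.
On this series the classical GM(1,1) reaches a maximum relative error of
0.28 (fitted-value denominator), concentrated after the break. The
Gaussian variant is *worse* here, not better: its equation-residual least
squares places the increment peak far from the data's early peak, and its
maximum relative error on this series exceeds 100%. A direct minimax
search over the entire anchored Gaussian family (a, b free; also μ, σ
free) bottoms out above 50% maximum relative error, so no parameter
choice for this model class fits the packaged series tightly — a useful
caution against expecting the Gaussian weighting to rescue a series with
a structural break. The GGM is the right tool for *smooth* rise-then-
decline series, which the synthetic generator produces and on which
parameter recovery is demonstrated.

## Grey relational analysis and the composite coefficient

Grey relational analysis (GRA) scores the similarity of each comparison
series xᵢ to a reference y. Series are first made dimensionless by
initial-value normalization (every series divided by its own first
element, so all start at 1). With deviations Δᵢ(k) = |y(k) − xᵢ(k)| and
global extremes m = minᵢminₖ Δᵢ(k), M = maxᵢmaxₖ Δᵢ(k) taken over the
whole panel, the relational coefficient and degree are

    ξᵢ(k) = (m + ρM)/(Δᵢ(k) + ρM),     γᵢ = (1/n)·Σₖ ξᵢ(k),

with resolution coefficient ρ ∈ (0,1), default 0.5. ξ is 1 exactly where
Δᵢ(k) equals a zero global minimum, and increasing ρ weakly increases
every non-minimal coefficient. The composite coefficient blends γ with
the sample Pearson correlation εᵢ:

    ρᵢ = φ·γᵢ + (1 − φ)·εᵢ,     φ ∈ [0,1], default 0.5.

Design choices where conventions genuinely diverge:

* **Normalization target.** Dividing each series by *its own* first
  element is the standard "dimensionless" step and keeps the analysis
  invariant to series ordering. A pointwise variant that divides all
  series by the first comparison series at each time point appears in
  some write-ups; it is order-dependent and kept only behind
  `normalize="first_series_pointwise"`.
* **What is normalized.** GRA (ξ, γ) uses the normalized panel; Pearson
  uses the raw series — it is invariant to per-series positive affine
  maps, so the choice is immaterial under initial-value normalization.
* **Extrema scope.** Both extremes are global over i and k within one
  reference panel, the literal double min/max.
* **Degenerate panel.** If every comparison coincides with the reference
  (M = 0), ξ ≡ 1 is returned as the continuous limit, with a warning.

The table builder assembles one block per statistic (γ, ε, ρ) across
several reference indicators sharing one comparison set, and appends a
*comprehensive index* row per block: the column mean over the reference
indicators (the published layout uses exactly three accident indicators —
death toll, deaths per 100 million yuan of GDP, deaths per 100,000
workers — against five economic indicators). Internal identities — the
comprehensive row is the block mean, the composite block is the exact
φ-blend of the other two — are asserted before any output is written.

The five economic indicator series behind the published coefficient table
were only ever released as charts, so the package ships the published
coefficients themselves as a fixture; its arithmetic identities (blend,
comprehensive means, range) are verified, while the γ/ε cells are pinned
by checksum, not recomputed.

## Synthetic data generator

The generator exists so every pipeline stage is testable without
downloads, emulating the two data shapes the models target:

* `economy_like` — value(k) = first·growthᵏ⁻¹·exp(ε), ε ~ N(0, noise_sd²):
  smooth multiplicative growth with lognormal noise, the shape of national
  consumption/wage/research series. Defaults: growth 1.08 (8% nominal
  annual growth, typical of the emulated economies over 2000–2020),
  noise_sd 0.02, n = 21 (a two-decade annual window).
* `accident_like` — increments of the anchored Gaussian grey cumulative
  with multiplicative noise; defaults a = 0.1, μ = 0, σ = 1 put the peak
  near k ≈ 3, echoing count series that peak early in a two-decade window.
  The default action quantity sets the saturation level b/a at 15× the
  first value so all increments stay positive.
* `grey_exact` — the noise-free anchored solution itself; refitting the
  GGM to this output recovers the development coefficient. The recovery
  tolerance frozen in the tests (2%) comes from a development-time oracle
  run: the observed deviation for the reference configuration
  (a = 0.05, n = 21) is ≈0.7%, reflecting that least squares on the
  *discrete* difference equation only approximates the continuous
  solution's parameters.

Noise is multiplicative lognormal, never additive Gaussian, so generated
series stay positive by construction. Each spec seeds its own
`numpy.random.default_rng` stream; there is no global state.

What the generator does **not** emulate: structural breaks (policy or
reclassification steps like the 2015→2016 drop in the packaged series),
business-cycle fluctuation around the growth trend, and cross-series
correlation beyond what shared shapes induce. Tests passing on synthetic
panels therefore demonstrate correctness of the machinery, not robustness
of grey models to break-laden real data — the packaged real series is the
honest counterexample and is exercised separately.

## Command-line interface

`greycast fit | forecast | gra | simulate` wrap the library thinly; all
commands are deterministic given their inputs (plus seed for `simulate`)
and repeated runs are byte-identical. Exit codes: 0 success, 1
usage/config error, 2 data error, 3 numerical failure. A YAML config file
can supply any option; explicit flags win.
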