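# Methods

This note documents the models, defaults, and design decisions behind
`ecosite`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Time grid and preprocessing

Scenes live on a strictly regular *k*-day acquisition grid (default
16 days, the Landsat TM revisit); the grid from 1984-05-21 to 2011-11-08
inclusive has exactly 628 steps. NDVI is the standard band ratio
(ρ_NIR − ρ_Red)/(ρ_NIR + ρ_Red); zero-denominator pixels are flagged
missing, never given a sentinel value — missingness is carried as an
explicit boolean mask throughout, because NDVI's physical range [−1, 1]
makes numeric sentinels collision-prone.

Gap infilling is linear in time between the bracketing observations.
Leading/trailing gaps are constant-extended from the nearest
observation rather than extrapolated: linear extrapolation can exit the
physical range, constant extension cannot. Filled series are clamped to
[−1, 1].

Seasonal-trend decomposition uses STL (the LOESS-based procedure) from
statsmodels with:

* **period = 23 steps** — 365.25/16 ≈ 22.83 scenes per year rounded to
  the nearest integer. The ~0.2 step/yr calendar drift is absorbed by
  the seasonal smoothing window.
* **seasonal window = 23 (odd)**, trend window at the STL default
  (≈ 1.5 periods). These are conventional defaults; no window values
  are prescribed by the protocol itself.
* After fitting, the seasonal component's global mean is shifted into
  the trend so the seasonal cycle averages exactly zero; additivity
  (trend + seasonal + remainder = input) is preserved to float
  precision.

The filtered series is trend + seasonal. The remainder carries sensor
noise plus whatever the smooth components could not fit; discarding it
raises the signal-to-noise ratio at the cost of a small, accepted loss
of genuine signal (the suite verifies the filtered series correlates
better with a known clean signal than the noisy input does at SNR 2).

## Classification

**Covariates.** One row per field sample, one column per scene date,
values from the filtered stack at the sample's pixel. Samples bind to
pixels through the affine geotransform (0-based, row-major, pixel-centre
coordinates).

**Feature selection.** Backward recursive elimination in fixed steps
(default 10): at each iteration the cross-validated accuracy of the
current subset is recorded, then the lowest-scoring covariates are
dropped. The importance score is a per-covariate class-separation
filter — the ratio of between-class variance (of class means,
sample-size weighted) to pooled within-class variance — recomputed each
iteration. This is a deliberate, visible design decision: the protocol
never defines its SVM-internal importance measure, and a filter score is
deterministic, fast, and reproducible. Zero-variance covariates score 0.
The selected subset is the iteration with the highest CV accuracy, ties
broken toward the smaller subset; the final ranking is a permutation of
1..n (drop order for eliminated covariates, final score order for
survivors).

**Classifier.** RBF-kernel SVM (scikit-learn SVC, one-vs-one
multiclass voting) inside a pipeline that standardizes covariates to
zero mean/unit variance — standard practice for RBF kernels, without
which the default power-of-two hyper-parameter grids are meaningless for
NDVI-scale inputs. Class weights default to inverse class frequency
normalized to mean 1, implementing "more emphasis on under-represented
classes" without inventing magnitudes.

**Tuning.** Exhaustive grid search over C ∈ {2⁻²..2⁸} and
γ ∈ {2⁻⁸..2²}, scored by cross-validated PCC. The internal CV uses
*repeated random 70/30 splits* — the same leave-group-out scheme as the
final validation — not stratified k-fold. This matters: balanced
stratified folds can score a degenerate (tiny C, tiny γ) machine
perfectly while it collapses to the majority class on unbalanced random
splits. Accuracy ties break toward smaller C, then smaller γ.
Hyper-parameters are tuned once on the full sample and held fixed across
validation repeats (the protocol's order of operations is ambiguous;
tuning inside every repeat would be defensible but costs an order of
magnitude more compute for no observed ranking change at these scales).

**Validation.** Leave-group-out CV: each repeat holds out
round(0.3·n) randomly drawn samples, fits on the rest, and predicts the
hold-out; all (prediction, reference) pairs across repeats pool into one
compiled error matrix (100 repeats of a 53-point hold-out from 176
samples pool 5,300 values). A split that leaves a class absent from
training is redrawn, up to ten times, with a log record. Note the
published SVM matrix sums to 4,970 while its accompanying text says
"n = 50/iteration" and 5,000 values — internally inconsistent; this
implementation documents its own rule (round(test_frac·n) per repeat)
rather than guessing.

## Accuracy decomposition

Error matrices are oriented rows = prediction, columns = reference (QD
and AD are orientation-symmetric; user's/producer's accuracy are not).
With p_ij the count proportions, p_i+ and p_+i the marginals, and
C = Σ p_ii:

* PCC = 100·C,
* UA_i = 100·p_ii/p_i+ (reliability), PA_i = 100·p_ii/p_+i
  (detectability); an empty marginal yields an undefined flag, never 0,
  because a silent 0 would distort class summaries (the bundled
  soil-survey matrix has two empty prediction rows),
* QD = ½ Σ|p_i+ − p_+i|, AD = Σ min(p_i+, p_+i) − C, and
  QD + AD = 1 − C exactly (asserted at 1e-12 on random matrices).

Reporting rounds half-away-from-zero: integer percent for PCC/UA/PA,
two decimals for QD/AD. This convention reproduces every published
value from the raw counts, including the 51.70% → 52 case where the
source's own table prints 51 in one place and 52 in another. Confidence
intervals for PCC are percentile intervals over the per-repeat values.

## Standardized precipitation index

Monthly totals (partial boundary months dropped) are accumulated over
rolling k-month windows, k ∈ 1..36. For each calendar month of the year
the accumulations are fitted with a zero-inflated gamma: H(x) = q +
(1 − q)·G(x), q the no-rain probability and G a gamma CDF fitted to the
positive accumulations by maximum likelihood (location pinned at zero),
falling back to Thom's moment approximation if the MLE fails. SPI is
the standard-normal quantile of H, so 0 is that month's median; fitted
CDF values are clipped to [1/(2m), 1 − 1/(2m)] (m = windows per month)
to keep quantiles finite. A month of year whose accumulations are all
zero is undefined; identical accumulations are a point mass whose
members sit at their median (SPI 0). Fewer than 30 accumulation windows
is an error — too few for a reliable fit. The construction makes SPI
invariant to rescaling all precipitation by a positive constant, and on
stationary simulated records it standardizes to ≈ N(0, 1) with
P(SPI ≤ −2) ≈ 0.023 (both verified in the suite).

Categories: ≤ −2 exceptionally dry, ≤ −1 dry, ≥ +1 wet, ≥ +2
exceptionally wet, else normal. Only the ±2 anchors are prescribed by
the protocol; ±1 is the conventional moderate-anomaly edge and is
configurable in transition detection. A *transition* is any defined
month whose dry/normal/wet band differs from the previous defined
month's; for multiple short scales the union of transition months is
used. Note a k-month window fully reflects a new regime only k−1
months after a switch, and in monsoon climates a regime change is
invisible until rain falls at all — the suite encodes both effects.

**Importance–transition alignment.** The protocol's original evidence
that important scenes follow climatic transitions is visual. The
quantitative restatement here — an extension, not a prescribed
procedure — takes the mean importance rank of scenes within w grid
steps at/after a transition minus the mean rank of all other scenes
(negative = post-transition scenes more important), with a one-sided
permutation p-value (≥ 999 label permutations, add-one corrected). If
the window covers every scene the statistic is 0 by definition.

## Synthetic scenes

The generator defines the study conditions for every end-to-end test.
Per pixel with class c and state s:

    NDVI(t) = b_c + A_c · m_s · S(doy t) · g(P̄_τc(t)) + ε(t)

* **S** — truncated cosine, max(cos(2π(doy − 260)/365.25), 0): a smooth
  unimodal bump peaking at day-of-year 260 (mid/late September, the
  C4-grass biomass peak) and zero through winter dormancy.
* **g(x) = (1 − λ) + λ·x/(x + h)** — saturating response to antecedent
  precipitation P̄_τ (mean mm/day over the preceding τ days); λ ∈ [0, 1]
  is the moisture sensitivity, h the half-saturation (1.5 mm/day).
* **ε** — i.i.d. Gaussian, clipped to [−1, 1].

Daily precipitation: Bernoulli occurrence at 45% within the 1 Jul–1 Oct
monsoon window and 8% outside, gamma(0.9, 4.4 mm) event sizes
(≈ 250 mm/yr, about two-thirds inside the monsoon — a Chihuahuan-desert
regime). Multi-year wet/dry regimes scale the amount distribution, so a
2× regime doubles expected monthly totals exactly in expectation.

The "paper-like" preset encodes five semi-arid classes. All share base
b = 0.13 — class identity lives entirely in the seasonal term, which is
what makes degraded states converge. Reference amplitudes A: Clayey
0.20, Loamy 0.28, Sandy 0.36, Shallow sandy 0.44, Deep sand 0.30.
Moisture response (λ, τ days): (0.95, 15), (0.80, 45), (0.65, 75),
(0.50, 30), (0.50, 150) — short-window, strongly responsive annual-grass
phenology at one end, deep-rooted buffered savanna at the other. State
multipliers m_s: grassland-reference classes decline 1.00, 0.95, 0.85,
0.70, 0.55, 0.40, 0.30 across codes 1–7; the savanna-reference class
rises 0.55 (state 3) → 0.70 → 0.90 → 1.00 (states 6+). The response
spreads are deliberately wide enough that the savanna reference state is
separable from grassland mid-states despite overlapping raw amplitudes;
with narrower spreads the generator fails its own separability
invariant.

Two qualitative orderings follow by construction: degradation shrinks
grassland amplitudes and grows savanna amplitudes; and because the
multipliers compress everything toward zero, class-mean series of
degraded states sit closer together than reference states — the
mechanism by which degraded sites misclassify. Defaults: noise
SD 0.02 ("low noise" settings; 0.04–0.05 for confusion studies),
missing rate 0–0.1, 30 m pixels.

What the generator does **not** emulate: reflectance-level physics,
spatially correlated noise or cloud structure, topographic effects,
within-class soil gradients, sensor calibration drift, or label error
in the field points. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the stated generative assumptions —
not field-data accuracy levels, which in the published study were set by
exactly the factors the generator omits (state undersampling, soil
characterization quality, registration error).

## Problem sizes in the test suite

End-to-end checks run at 64×64 pixels × 628 scenes with 50 samples per
class for the recovery test, and ten repeats at 30×30 × 491 scenes for
the degraded-state study — sizes chosen so the pixelwise STL pass (the
dominant cost, ~15 ms/series) keeps the whole suite in a few minutes on
one CPU while leaving every stage of the pipeline exercised at full
temporal resolution.

## Known limitations

* The per-pixel STL loop is pure Python over pixels; scenes much beyond
  ~10⁵ pixels want chunked/parallel execution that is out of scope here.
* RFE's filter importance is univariate; covariates informative only in
  combination can be eliminated early.
* The optional 3×3 majority spatial filter discussed in the source
  protocol is deliberately not applied anywhere (its published numbers
  are unfiltered); prediction maps are raw pixelwise outputs.
* SPI at sub-monthly scales is unsupported by design (unreliable in
  arid records); scales are capped at 36 months.
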