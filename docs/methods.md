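# Methods

## Scoring rules

The three Neck Disability Index scorings share the item bank (10 items,
six ordered response options scored 0–5) and a common 0–50 reporting
scale:

| version | items | recode | ordinal range | 0–50 mapping |
|---|---|---|---|---|
| NDI-10 | all 10 | none | 0–50 | identity (ordinal) |
| NDI-8 | all but *headaches*, *lifting* | none | 0–40 | transform table |
| NDI-5 | *personal care*, *concentration*, *work*, *driving*, *recreation* | driving 0,1,2,3,4,5 → 0,1,2,3,3,4 | 0–24 | transform table |

The driving recode collapses the top two response options because the
item's Rasch step thresholds are disordered — category 4 is never the
most probable response at any severity, so categories 4 and 5 carry the
same information.

A transform table maps every integer ordinal sum to an interval-level
score. Validation requires completeness over the ordinal range, weak
monotonicity, and anchored ends (0 → 0, max → 50). The genuine Rasch
score-to-measure tables for NDI-8 and NDI-5 are published only as study
supplements, so the engine takes them as configuration; when none is
supplied it falls back to the linear rescale `sum × 50/max`, and every
output records the table's provenance label so placeholder-scored results
cannot be mistaken for Rasch-scored ones. Missing responses are a hard
error by default; an optional proration mode (mean of answered items
carried to the full item count, i.e. `sum × k_total/k_answered` before
transformation) exists but is off by default so the published scoring
rule is never silently altered.

Transformed scores keep full floating precision internally; only the
report layer rounds, to one decimal.

## Agreement statistics

For a method pair `(a, b)` with the first method as reference:
`D = a − b`, `A = (a + b)/2`.

* **Bland–Altman**: bias `d̄ = mean(D)`, `SD = sd(D)` with the sample
  (n−1) denominator, limits of agreement `d̄ ± z·SD` with `z = 1.96` by
  default (configurable). The LoA multiplier is the fixed normal
  quantile, not a t quantile — the convention of the agreement
  literature.
* **Inference on the bias**: `SE = SD/√n`, one-sample t statistic
  `d̄/SE` with `df = n − 1` and a two-sided p from the t distribution.
  The 95% CI of `d̄` uses `±1.96·SE` by default; a t-quantile CI is
  available (`ci_method="t"`), the two differ visibly only at small n.
* **Wilcoxon signed-rank**: zero differences are dropped before ranking
  (Wilcoxon's original rule; the Pratt variant is available), absolute
  differences receive midranks on ties, and `W = min(W⁺, W⁻)`. The p
  value is exact — the full sign-flip null distribution of `W⁺`, built
  by dynamic programming over the (doubled, so midranks become integers)
  ranks — whenever at most 20 nonzero differences and no ties are
  present; otherwise a normal approximation with continuity correction
  and variance `Σrᵢ²/4` (algebraically the textbook tie-corrected
  variance) is used. The two-sided exact p is
  `min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)))`.
* **Regression-based LoA** for magnitude-dependent bias: OLS of `D` on
  `A`, residual SD with the n−2 denominator, band
  `b₁·A + b₀ ± 1.96·SD_res` (constant width). The band is plotted over
  the observed range of `A` only. Degenerate inputs: constant `A` or
  fewer than 3 pairs are errors; a zero-variance `D` yields a flagged
  degenerate Bland–Altman result with undefined t.
* **Normality diagnostics**: histogram of `D` plus sample skewness and
  excess kurtosis; bias-transform helpers (`log(x + offset)` with a
  default offset of 1 to admit zero scores, and affine rescales) support
  attempts to normalise a non-uniform bias pattern.

Antisymmetry under method swap (d̄, t and the LoA mirror with sign),
location invariance, and CI-inside-LoA nesting are enforced by property
tests.

## Synthetic respondents

Item responses are simulated from a **partial credit model**: person
severity θ ~ Normal(θ_mean, θ_sd²) on the logit scale, and

    P(X = x | θ) ∝ exp( Σ_{k≤x} (θ − δ_k) ),   x = 0..5,

with the empty-sum convention at x = 0, evaluated through a max-shifted
softmax so probabilities are stable for |θ|, |δ| up to at least 30
logits.

Defaults emulate the frame of a community neck-pain cohort: n = 201,
158/201 female, ages 19–74. Step difficulties are evenly spaced
(−2, −1, 0, 1, 2) logits for every item except driving, whose top two
steps are swapped (−2, −1, 0, 2, 1) to reproduce the disordered
thresholds that motivate the NDI-5 recode. The latent distribution
(θ_mean = −1.04, θ_sd = 1.23) is a **calibration**, solved by
Gauss–Hermite quadrature root-finding so the simulated NDI-10 total has
mean ≈ 16.4 and SD ≈ 10.0 — the summary moments such cohorts report.
Two moments cannot pin down 50 step parameters, so the simulator matches
the analysed cohort only in scale location/spread and in the driving
item's pathology, not in item-level response distributions, inter-item
residual structure, or demographic–severity correlation. Passing tests
therefore demonstrate that the pipeline's arithmetic and statistical
machinery are correct on data with the assumed structure, not that any
particular published cohort value is recoverable.

`paired_shift_fixture(n, delta, sigma, seed)` builds a method pair with a
known additive shift: `a` is the simulated NDI-10 score, `b = a + δ +
Normal(0, σ²)` clipped to [0, 50]. Clipping at the scale ends biases the
recovered bias slightly (the count of clipped values is reported as
`n_clipped`); at the default severity calibration with δ = 2.3, σ = 5
about 6 of 201 values clip and the bias is ≈ 0.06 points.

All randomness flows through a single `numpy.random.Generator` seeded
from the config — no global state; identical configs are bit-reproducible
end to end, which the CLI check (`all --seed S` twice → byte-identical
report) verifies.

## Numerical and design choices

* Sample SD (n−1) everywhere; at n = 201 the alternative denominators
  differ negligibly but tests need one fixed convention.
* 1.96 rather than t(200) ≈ 1.972 for the default CI of the bias: at
  n = 201 the two agree to one decimal on 0–50-scale data, and the fixed
  quantile matches how agreement tables are conventionally reported.
* Exact-vs-approximate Wilcoxon threshold at 20 nonzero differences:
  2²⁰ enumeration is instant via the DP, while typical cohort sizes
  (n ≈ 200) fall to the approximation, consistent with mainstream
  statistical software defaults.
* Report parity: table outputs round to one decimal and p values below
  0.001 print as `<0.001`.
* Problem sizes in the checks — 500 replicates of n = 201 for shift
  recovery, 10⁴ respondents for the calibration check, 200 enumeration
  cases at n ≤ 10 — were chosen to keep Monte-Carlo error well below the
  assertion tolerances (e.g. the mean-score check allows 4 standard
  errors ≈ 0.4 points at n = 10⁴).

## Known limitations

* With linear placeholder transforms the three simulated versions agree
  nearly perfectly (bias ≈ 0): the systematic inter-version bias seen in
  real cohorts arises from the curvature of the genuine Rasch
  score-to-measure tables and from real item-response patterns, neither
  of which the placeholder reproduces. Supply real tables to study real
  disagreement.
* The simulator draws items independently given θ (local independence
  holds by construction); real questionnaire data may violate it.
* Published agreement-table cells can only be audited for internal
  arithmetic consistency (`BAStats.from_summary`); reproducing them
  outright requires the original patient-level data, which is not
  deposited.
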