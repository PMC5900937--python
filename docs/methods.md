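# Methods

## Data model

The analysis unit is a binary transaction matrix: n patients by m screening
items, cell = 1 when the screen is present in the chart within its lookback
window (2 years for vitals, 3 years for laboratory tests, any time in the
summary profile for lifestyle items — windows are catalog metadata, not
computed here). Absence of a record is encoded 0; there is no missing-data
state, because presence of the screen is itself the outcome. The default
catalog has 9 items in 3 clinical categories: vitals = {BP, BMI, WC},
laboratory = {LDL, A1c}, lifestyle = {smoking, alcohol, diet, exercise}.
Files are plain CSV with a header row, a leading `patient_id` column and
strict "0"/"1" cells — unambiguous and diffable.

## Rule mining

Apriori runs level-wise with lexicographic candidate generation and
downward-closure pruning; supports are counted by intersecting boolean
indicator columns, which is exact and more than fast enough at m = 9
(no transaction-list compression). The support threshold comparison is
inclusive: an itemset at exactly σ is frequent. Defaults σ = 0.02 and
κ = 0.80 are the study's operating point. A brute-force subset enumerator
(m ≤ 16) serves as the independent oracle in tests.

Rules are single-consequent: each frequent S with |S| ≥ 2 yields candidates
S∖{b} → {b}. Scoring uses full-precision probabilities throughout; rounding
to 2 decimals (or 1 decimal for category percentages) happens only at
report time, because recomputing from rounded intermediate values visibly
perturbs lifts at the third decimal.

### Standardized lift

ν = 1/max{P(A), P(B)} is the Fréchet upper bound on the lift; λ is the
maximum of four lower bounds — the Fréchet floor (P(A)+P(B)−1)/(P(A)P(B)),
two support-threshold floors 4σ/(1+σ)² and σ/(P(A)P(B)), and the
confidence-threshold floor κ/P(B). For any rule satisfying both thresholds,
λ ≤ L ≤ ν (property-tested on synthetic data), so L* = (L−λ)/(ν−λ) ∈ [0, 1].
When ν = λ the value is undefined and reported as such (never a numeric
0/0); ranking places undefined values last. Ranking is by descending L*,
ties broken by descending support then lexicographic antecedent, so output
order is deterministic under input permutation.

### Pruning

Within each consequent cluster, a rule whose antecedent is a proper subset
of another member's antecedent is removed; the *super* rule (larger
antecedent) is kept. Note this is the reverse of some conventional
redundancy definitions that keep the more general rule; here the longer
rule is the informative one for alert design, since it pins down the exact
item combination. Equal antecedents cannot occur (rules are unique by
construction). Pruning is selection only — retained metrics are not
recomputed — and is idempotent.

### Multilevel rules

Categories are collapsed with an any-member OR, then the identical
apriori + rule machinery runs on the 3-column matrix. Category rules are
ranked by lift (standardized lift is computed and carried but is not the
ranking key at category level, matching the reporting convention for such
tables); support/confidence are reported as percentages to 1 decimal.

## Latent structure

**Tetrachoric correlation** is estimated by two-parameter profile ML:
thresholds are fixed at the inverse-normal quantiles of the observed
margins and the likelihood of the 2×2 table is maximized over ρ alone
(bounded scalar optimization on [−0.999, 0.999], xatol 1e−8). Bivariate
normal rectangle probabilities are evaluated in closed form via Owen's T
function, which is deterministic and accurate to ~1e−15 over the whole
correlation range. A zero cell triggers a 0.5 continuity correction to
every cell, flagged in the result. The pairwise matrix is symmetrized and,
if its smallest eigenvalue falls below 1e−6, smoothed by eigenvalue
clipping (with diagonal rescaling to 1) and flagged.

**Factor extraction** is iterated principal-axis: the correlation diagonal
is replaced by communality estimates (initialized at squared multiple
correlations, with a max-|row correlation| fallback if inversion fails),
the reduced matrix is eigendecomposed, and communalities are recomputed
from the leading 3 components until max |Δh²| < 1e−6 or 200 iterations.
Communalities reaching 1 are clamped at 0.999 and flagged (Heywood).
Non-convergence is flagged with the iteration count, never silent. One
practical caveat: the laboratory factor has only 2 indicators, which leaves
its two communalities identified only through their product; on sampled
data the iteration then drifts along a near-ridge and routinely hits the
iteration cap with the convergence flag false while loadings are stable to
3-4 decimals. The strict tolerance is kept because the flag is informative,
not an error.

**Rotation** minimizes the oblimin criterion with γ = 0 (quartimin) by
gradient projection, from the identity start plus 5 seeded random
orthonormal starts, keeping the lowest criterion value. Presentation is
made deterministic by sign-fixing each factor (nonnegative loading sum) and
ordering factors by explained sum of squares. The reproduced correlation
matrix LΦLᵀ is invariant under the rotation (≤ 1e−8, asserted in tests).
Items are assigned to the factor with the largest absolute pattern loading;
exact ties break to the lower factor index and are flagged, as are all-zero
rows.

**Cronbach α** uses population (divide-by-n) variances for both the item
variances and the total-score variance; the convention cancels in the
ratio and is held consistently. α = 1 exactly for duplicated items, ≈ 0
for independent items.

## Synthetic cohort generator

A latent-probit (Gaussian copula) mechanism: z ~ N(0, ΛΦΛᵀ + Ψ) with
Ψ = I − diag(ΛΦΛᵀ), and item j present iff z_j exceeds the upper-tail
normal quantile of its target prevalence. This makes the tetrachoric /
factor model literally true in simulation, so recovery tests have an exact
ground truth (`ground_truth_tetrachoric` returns ΛΦΛᵀ + Ψ). All draws come
from one `numpy` Generator seeded from the config; identical configs give
identical cohorts.

Study defaults: the 9 published item prevalences (0.036 for diet up to
0.820 for BP, as counts out of 92 140); one-factor-per-item loading blocks
vitals (0.75, 0.80, 0.65), laboratory (0.85, 0.85), lifestyle (0.70, 0.75,
0.60, 0.65); factor correlations vitals–laboratory 0.40 and 0.35 for the
two lifestyle pairings. The loadings were chosen once so that within-
category latent correlations are strong (the laboratory pair's population
tetrachoric is 0.85² = 0.72, the dominant pair) and factors are moderately
positively correlated, qualitatively matching the published grouping; no
population correlation values are published, so the calibration is
qualitative by necessity. What the generator deliberately omits: patient
covariates (age, sex, chronic conditions, visit counts), provider/practice
clustering, and any missingness mechanism. Passing recovery tests
therefore demonstrates correctness of the algorithms under the latent-
normal model, not robustness to real-EMR features such as informative
recording or clustered practice styles.

## Problem sizes and numerical choices in tests

Calibration and recovery tests run at n = 100 000 (marginals within
±0.005, tetrachoric recovery within ±0.05 across prevalences 0.04–0.82,
factor congruence > 0.95 with exact category assignment); the end-to-end
determinism check runs the full pipeline twice at the study size
n = 92 140 and compares output bytes. The Apriori-vs-oracle property is
checked on 100 random seeded matrices with up to 12 items. These sizes
keep the whole suite around a few seconds while leaving the statistical
tolerances comfortably non-trivial.

## Known limitations

- Tetrachoric pairs are estimated independently; the smoothed matrix is
  not a joint ML estimate of a correlation matrix.
- Two-indicator factors (the laboratory block) are only weakly identified
  in exploratory factoring; see the convergence caveat above.
- The pruning rule is exactly subset-maximality per consequent; no
  confidence-improvement or other pruning variants are offered.
- Only lift and standardized lift are implemented as interestingness
  measures (no leverage, Gini index, or Yule's Q), and no confirmatory
  factor analysis or fit indices beyond residual norms.
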