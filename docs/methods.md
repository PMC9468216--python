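# Methods

This note records the statistical procedures the package implements, the
defaults it ships, and the design decisions taken where more than one
reasonable choice existed. It documents what the code computes; every
number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Variables and codings

Eleven categorical variables in fixed order: physical activity (3 levels),
sex (2), age band (4), education (4), residence (4), marital status (4),
night sleep band (5), nap band (3), smoking (2), alcohol (2), and the MMD
outcome (2). The machine-readable codebook
(`src/mmdbn/data/codebook.json`) is the single source for codes and
labels; `validate_dataset` checks any input table against it without
mutating data. Missing cells carry the sentinel −1, outside every domain.

Derivations:

- **MMD** = 1 iff ≥ 2 of the 14 chronic-condition indicators are set —
  monotone in the number of positive indicators by construction.
- **MET-minutes/week** = Σ over intensity levels of weight × days/week ×
  minutes/day, weights 8.0 (vigorous), 4.0 (moderate), 3.3 (light); at
  most one record per intensity.
- **Activity band**: light < 600, moderate [600, 3000), vigorous ≥ 3000
  MET-min/week. The middle band is half-open so that 3000 falls in
  "≥ 3000", which the upper bound states explicitly.
- **Band boundaries** elsewhere follow the coding table rather than prose
  labels where the two disagree: a 30-minute nap codes 2 ("≤ 30 min"),
  sleep bands are ≤5/≤6/≤7/≤8/>8 h, age bands ≤55/≤65/≤75/>75 years.
- Unrecognized raw labels code as missing with a warning instead of
  raising, so one bad cell never drops a record.

## Synthetic cohorts

`charls_like_network()` is a fixed 11-node, 18-edge ground-truth network.
Ten edges are those documented for the study system (age, sleep and
physical activity as parents of MMD; age → physical activity; sex and age
into education and marital status; education → residence; residence →
sleep). The remaining eight (age → residence, age → nap, nap → sleep,
education → physical activity, sex → smoking, age → smoking, smoking →
alcohol, sex → alcohol) are plausible lifestyle links frozen in
`GROUND_TRUTH_EDGES` so that tests have a single fixed truth.

CPT rows follow a log-linear association model: row(child | parents) ∝
t(child) · exp(Σₚ βₚ · z(parent) · z(child)) with centred category scores
z ∈ [−1, 1] and per-edge coefficients β chosen so every edge is
detectable at n = 20,000. The base weights t are then rescaled by
iterative proportional fitting until each node's implied marginal equals
the pooled baseline-table frequency (tolerance 1e−12), which pins
P(MMD = 1) = 0.538 exactly. Ancestral sampling is vectorized
inverse-CDF draws in topological order; identical seeds give identical
frames.

What the generator emulates: the categorical marginals of the published
cohort and a dependence structure of realistic strength. What it does
not: the survey's multi-stage stratified sampling and household
clustering, within-stratum joint structure beyond the 18 edges, and any
temporal dynamics. Passing recovery tests on these cohorts therefore
shows the algorithms work under faithful, moderately-strong dependence —
not that the published edge set is the true epidemiological structure.

Missingness injection supports MCAR (independent Bernoulli at the target
rate) and MAR, where the mask probability is logistic in the driver
column's centred score with the intercept solved (Brent) to hit the
requested overall rate; the driver itself is never masked.

## Imputation

`rf_impute` is the iterative missForest scheme: initialize missing cells
with column modes (ties to the smallest code), then revisit columns in
increasing-missingness order, refitting a random-forest classifier (100
trees, √p features per split, Gini) on the rows observed for that column
and predicting its missing cells. Iteration stops when the fraction of
imputed cells that changed stops decreasing — returning the previous
iterate — or at 10 passes. Observed cells are bit-preserved. The forest
is scikit-learn's RandomForestClassifier behind a factory argument, so a
different learner can be swapped in. On a 10%-MCAR cohort of 10,000 the
forest imputes ~64% of held-out cells correctly versus ~55% for
mode-fill; the gap is the dependence structure the forest exploits.

## Logistic baseline

Predictors enter as single integer scores (one odds ratio per variable,
interpreted per category step), matching the one-row-per-variable forest
plot; one-hot dummy coding is available via `dummy_code`. Fitting is
damped Newton/IRLS on the Bernoulli log-likelihood; convergence requires
the largest score-equation component below 1e−10, and the line search
tolerates 1e−10 of log-likelihood noise so it cannot stall at the
optimum. Standard errors come from the inverse observed information;
intervals are Wald, exp(β ± 1.96·SE). Perfect or quasi-perfect
separation (constant outcome, diverging coefficients, singular
information) is flagged and returns a partial fit with a warning rather
than raising. The saturated 2×2 fit equals the cross-product odds ratio
to 1e−6; coefficients and standard errors agree with statsmodels in the
test suite.

## Structure learning

- **CI test**: G² likelihood ratio, 2 Σ O ln(O/E) summed over
  conditioning strata, df = (|X|−1)(|Y|−1)Π|Zᵢ| with category counts
  fixed from the full dataset so subsamples cannot shrink df. Pearson X²
  is an option. A test with n < 5·df is skipped and treated as
  independence — the standard guard against unreliable high-order
  conditional tests. Empirical type-I error at α = 0.05 is 4–7% over 500
  independent replicates of n = 2,000.
- **MMPC**: forward max-min growth, backward subset pruning, AND-rule
  symmetrization. Association is the p-value with the negated G²
  statistic as tie-break, because p-values saturate at 0 under strong
  dependence. Conditioning sets are capped at 3 (configurable) — ample
  for 11 variables.
- **Score**: BIC with (ln n)/2 penalty, decomposable and cached per
  (node, parent set).
- **Hill climbing**: plain greedy from the empty graph — add inside the
  skeleton, delete, reverse — applying the single best strictly-improving
  move per iteration. Score-equivalent orientations differ only by float
  noise, so deltas within 1e−6 count as ties and the first move in
  sorted order wins; this keeps runs bit-reproducible and stops
  equivalence-class ties from being decided by rounding. No tabu list or
  restarts: greedy can end in a local optimum (the 4-node sprinkler
  benchmark's near-deterministic gate is a reproducible example, where
  the skeleton is exact but the chosen orientation class is wrong);
  chain, fork and collider benchmarks are recovered exactly at
  n = 20,000.
- **Evaluation**: CPDAGs via v-structure orientation plus Meek rules
  R1–R3; SHD counts per-pair edge-type disagreements; skeleton F1
  against the generating DAG. At n = 20,000 the study network's skeleton
  F1 is ≥ 0.94 across seeds and the median CPDAG-SHD falls as n grows
  through 1k/5k/20k.
- MMD is an ordinary node — no outcome-orientation constraint — which is
  what lets the learned graph give it parents.

## Inference

`eliminate_query` reduces CPT factors by the evidence, eliminates hidden
variables in greedy min-fill order (lexicographic ties), multiplies the
remainder and renormalizes. Zero-probability evidence raises an explicit
error instead of propagating NaN. `enumerate_joint` materializes the full
joint (capped at 10⁷ states, refusing above) and is the independent
oracle: across exhaustive benchmark queries and the 184,320-state study
network the two routes agree within 1e−10 (measured ~2e−16).
`joint_probability` accumulates in log space to avoid underflow.

## Parameter learning

`fit_mle` computes CPT rows as conditional frequencies, with optional
Laplace smoothing (default 0, pure MLE); unobserved parent
configurations get a uniform row and a log message. A caveat that
follows from the calibrated marginals: the published cohort contains
sub-1% categories (education ">college" 0.85%, residence "special"
0.44%), so some parent configurations have joint probability ~2e−4 and
only tens of rows even at n = 100,000. Worst-case CPT recovery error at
that size is therefore dominated by small-sample noise in those rows
(~0.15 observed), while the support-weighted mean error is ~0.002. Users
fitting families that include rare-category parents should either smooth
(`pseudo_count > 0`) or read low-support rows with caution.

## Pipeline and reproducibility

`run_pipeline` executes impute → summarize → logistic → MMHC → MLE →
marginals/queries, writing CSV/DOT/BIF artifacts plus a JSON config and
convergence report; all randomness derives from one config seed through
named sub-streams, and re-running a persisted config reproduces text
artifacts byte-identically. Stratified summary percentages round half-up
to 1 dp, the published table's convention.

Problem sizes used by the test and acceptance runs — 20,000-row cohorts
for structure recovery (1k/5k/20k for the sample-size sweep, 3 seeds),
100,000 for parameter recovery, 10,000 at 10% MCAR for imputation, 500
replicates of 2,000 for test calibration — are chosen so each check is
statistically meaningful at desk scale.

## Known limitations

- Cross-sectional data: learned edges are dependence, not causality, and
  orientation within a Markov-equivalence class is partly arbitrary.
- Greedy search has no optimality guarantee (see the sprinkler example);
  restarts/tabu were deliberately left out to keep runs reproducible.
- The published posteriors for the sequential-evidence narrative depend
  on the original microdata CPTs; the package reproduces the pattern
  (risk rising from the 0.538 prior as adverse evidence accumulates),
  not those exact values.
- Continuous variables, approximate inference, survey weights and
  do-calculus are out of scope.
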