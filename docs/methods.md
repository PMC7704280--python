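# Methods

## Threat model and risk quantity

The adversary holds only the released synthetic sample `S` (the generative
model is never shared) and background knowledge of people's
quasi-identifiers, either about acquaintances or from a population registry.
Identification of a synthetic record goes *through* the real sample
`R ⊆ P`: a synthetic record can only point at a real person if a real-sample
record shares its quasi-identifier tuple. Two directions are modelled — pick
a random population member and look for them in the data
(population-to-sample, risk `A`), or pick a matched real record and look the
person up in a registry (sample-to-population, risk `B`). The adversary
attempts one direction, unknown to the custodian, so the reported risk is
`max(A, B)`, maximized further over attack modalities (below).

Identification alone is not the harm; the model multiplies each matched
record's term by `R_s`, an indicator that the adversary would actually
*learn something new and correct* from the attached sensitive values. The
whole quantity is therefore a probability of *meaningful* identity
disclosure per randomly targeted individual, in `[0, 1]`, compared against
an acceptability threshold (default 0.09, the value used by large health
data custodians for public releases; equality is acceptable).

## Matching

Equivalence classes are formed by exact equality on the tuple of active
(possibly generalized) quasi-identifier values — a hash join, verified in
the test suite against an O(n·m) nested-loop oracle. Adversary imperfection
is deliberately *not* modelled by fuzzy matching; it enters through the λ
adjustment instead. Raw continuous quasi-identifiers are refused (equality
on floats is degenerate); they must be binned through a hierarchy level.
Population class sizes `F_s` come from a supplied population table, which
removes estimation error from the assessment; estimating `1/F_s` from the
sample alone is out of scope.

Missing values: a record missing any active quasi-identifier is treated as
a unique sentinel — it matches nothing, with `f_s = F_s = 1` and `I_s = 0`.
This avoids fabricating matches. Missing sensitive values are skipped in
the learning test and removed from the L% denominator for that pair.

## The λ adjustment

A suspected match fails if the data held an error on any of the `k`
matching variables, or if the adversary cannot verify the match. Health-data
error rates have a weighted mean of 4.26% per variable; published
re-identification attempts could verify suspected matches about 23% of the
time. Both rates are uncertain, so they are modelled as triangular
distributions — a standard choice in risk assessment when only a central
value and plausible bounds are known. The cited values are taken as the
modes with symmetric ranges clipped at zero: error (0, 0.0426, 0.0852),
verification (0, 0.23, 0.46); because the ranges are symmetric, mode and
mean coincide, and both distributions are configuration-overridable.

Errors and verification are not independent — errors make verification
less likely — so draws are coupled with a medium negative rank correlation
(|ρ| = 0.3 per Cohen's effect-size guideline) through a Gaussian copula.
The copula normals use Pearson correlation `2·sin(π·ρ/6)` so that the
induced Spearman correlation is exactly −0.3 in distribution while leaving
the triangular marginals untouched (verified by Kolmogorov–Smirnov at
10⁵ draws, D < 0.01).

One `(e_s, v_s)` pair is drawn per real record per assessment run;
`λ_s = v_s (1−e_s)^k`. Using `λ_s` directly could over-attenuate the risk,
so the conservative `λ_c = (λ_s + 1)/2` — the midpoint between `λ_s` and
the no-attenuation value 1 — is what enters the sums; `λ_c ∈ (0.5, 1]`
always.

## Learning something new

A matched pair teaches the adversary something when the real value is
unusual in the real sample (otherwise little is gained) *and* the synthetic
value is close to it (otherwise what is "learned" is wrong). Per sensitive
variable:

- **Nominal/binary** (binary is treated as nominal throughout): with `p_j`
  the real-sample share of the record's value, learning requires value
  agreement and `(1−p_j) > sqrt(p_j(1−p_j))`, i.e. the weighted similarity
  exceeds one Bernoulli standard deviation. For exact matches this is
  algebraically equivalent to `p_j < 1/2`, which the tests assert on a grid.
- **Continuous**: the variable is discretized by univariate k-means to get
  the record's cluster share `p_s` (the distance weight is `p_s` itself, as
  specified for this test), and learning requires
  `p_s·|X_s − Y_t| < 1.48·MAD`, the MAD taken over the variable in the real
  sample. 1.48·MAD equals one standard deviation under normality; the
  multiplier is configurable since one SD is a deliberate, conservative
  choice.

The cluster count is chosen by a majority rule over a panel of four
indices — within-SS elbow (maximum curvature), silhouette,
Calinski–Harabasz and Davies–Bouldin — over k ∈ [2, min(10, #distinct,
n−1)], ties toward smaller k. A larger index panel exists in the clustering
literature; four well-separated voters keep the choice reproducible and
dependency-light, and the panel is extensible. k-means uses deterministic
sorted-quantile seeding, so discretization needs no random seed.

`R_s = 1` iff for **any** matched synthetic partner at least `L`% (default
5) of the applicable sensitive variables pass. Degenerate cases are
conservative: a pair with zero applicable sensitive variables — in
particular a dataset with no sensitive variables — counts as learned, and
the report flags that the assessment degraded to pure identity disclosure.
`R_s` is only computed where `I_s = 1`; tests confirm this equals computing
everywhere and masking.

## Attack search

The adversary may match on any non-empty subset of the quasi-identifiers,
at any generalization level per variable (level 0 = raw). Built-in
generalization operators: numeric bands of configurable width, string
prefixes, full suppression, explicit value maps, and explicit bin edges.
Real, synthetic and population tables are generalized identically, so
matching stays equality-on-tuple; sensitive variables are never generalized
(after a match the adversary reads them at the released granularity). Risk
is not monotone in the subset — dropping a variable gains synthetic matches
but also inflates class sizes — so no pruning is attempted: the search is
exhaustive up to a cap (default 10,000 configurations); when truncation is
enabled the all-variables configuration and every single-variable
configuration are always retained. One set of per-record `(e_s, v_s)` draws
is shared across configurations (only `k` changes), so the argmax reflects
the attack surface rather than sampling noise.

## Sequential tree synthesizer

Variables are generated one at a time along a sequence (default: column
order; configurable — no automatic sequence optimization is attempted).
The first variable is resampled from its empirical marginal; each later
variable is modelled by a decision tree with all earlier variables as
predictors, and a synthetic value is drawn uniformly with replacement from
the training values in the predicted terminal node. Trees are scikit-learn
CART (classification for nominal/binary targets, regression partitions for
continuous ones) with `min_samples_leaf` default 5 and no depth cap; the
synthesis contract — partition the predictor space and sample from the
node — is agnostic to the specific partitioning algorithm, and
conditional-inference-style trees could be substituted. Continuous leaves
resample observed values rather than smoothing parametrically, so synthetic
nominal categories are always a subset of the real ones. Categorical
predictors are ordinally encoded; a category unseen at fit time is encoded
as the modal training category, which routes it down the majority path.
The minimum leaf size is the privacy dial: leaves of size 1 on near-unique
data reproduce training records (high measured risk), larger leaves pool
them.

## Fixture generator

The fixture module emulates the *structure* the assessment exercises:
categorical quasi-identifiers with controlled uniqueness (forced exact
class counts, all-distinct columns, skewed marginals), sensitive variables
as categorical tables or Gaussian mixtures, optional one-parent conditional
tables, and simple-random-sample drawing at a configurable fraction
(defaults emulate a 10–20% sampling regime typical of the datasets this
kind of assessment targets). Control "synthesizers" (copy / permute /
independent) bracket the metric: copy must equal the real-data baseline,
independent resampling must score lower on highly identifiable data. The
generator does **not** emulate real health data's missingness patterns,
longitudinal structure, measurement error or inter-variable correlation
beyond one conditional layer — so green tests demonstrate the metric's
internal correctness and directional behaviour, not the risk level of any
real dataset.

## Numerical and scale choices

- Engine sums are vectorized and are required (tests) to match a
  straight-line per-record transcription to 1e−12.
- Worked-example incomes are held in thousands (70 = 70k), consistently
  across tables and tests.
- Problem sizes in the tests and acceptance script (populations of a few
  hundred to 2,000, 10⁵ Monte-Carlo draws, 20-seed ordering checks) were
  chosen so each property is measured well inside its tolerance while the
  full suite stays fast; all are package choices, not statements about
  real deployments, which this model handles at 10⁵–10⁶ records.

## Limitations

- Cross-sectional data only; no longitudinal/event-level support.
- The adversary's own background knowledge is assumed error-free
  (conservative).
- Population class sizes must be supplied; no sample-based estimation of
  population uniqueness.
- No confidence intervals on the risk: λ sampling variability can be
  explored by re-seeding, but the reported value is a point estimate.
- Membership disclosure and attacks with white/black-box access to the
  generative model are complementary analyses outside this package's scope.
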