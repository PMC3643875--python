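# Methods

## Model and decision framework

A continuous outcome with clustering is modelled as

    y_ij = α + β·x_ij + u_j + e_ij,

with patient *i* in cluster *j*, binary treatment indicator `x_ij`, cluster
effects `u_j ~ N(0, σ²)` and errors `e_ij ~ N(0, 1)`, drawn independently.
The error variance is fixed at 1 without loss of generality (rescaling both
components leaves every test statistic unchanged), so the intraclass
correlation is ρ = σ²/(σ²+1) and `icc_to_cluster_variance` inverts this as
σ² = ρ/(1−ρ).

The true variance of the treatment-effect estimator decomposes as
Var(β̂) = V0 + VE, with V0 the usual no-clustering variance and VE a signed
correction that vanishes when either the ICC or the within-cluster
correlation of treatment assignments is zero. When both are non-zero the
model-based standard error of the unadjusted analysis is biased — downward
(inflated type I error) for positive assignment correlation, upward
(conservative) for negative — and the clustering is *non-ignorable*.

`classify_source` encodes the resulting decision rules for a declared
clustering source:

* ICC assumed zero → ignorable. Since the ICC is rarely known in advance,
  and estimating it from trial data to decide the analysis inflates error
  rates, `unknown` is conservatively treated as non-zero.
* Pre-randomisation clustering → non-ignorable iff the cluster was used in
  the randomisation (stratification/balancing). For block-based balancing the
  assignment correlation is −1/(n−1) (block size n), so the sign is negative
  and the consequence conservative. For non-block balancing methods such as
  minimisation the sign is not determined by theory; the verdict is still
  non-ignorable, with sign `unknown` and consequence `invalid`. The
  `balancing` field defaults to `permuted_blocks` because stratified
  randomisation in practice almost always means permuted blocks within
  strata.
* Post-randomisation clustering → non-ignorable iff arms are assigned to
  clusters with unequal probabilities (`unequal_probability` or
  `single_arm`), giving a positive correlation and an inflated type I error.

The empirical assignment-correlation estimator pools all within-cluster
pairs of distinct patients and computes the Pearson correlation of the pair's
two arm indicators (each unordered pair counted symmetrically; reduces to
cluster-level sums). It is consistent but carries an O(1/N) finite-sample
bias of roughly −1/(N−1) from plugging in the sample mean — the same
phenomenon as in ANOVA ICC estimators — so agreement checks against the
closed forms use one large pooled sample rather than averages of many small
samples.

## Simulator

Patients are allocated 1:1 (`forced_equal`: a random permutation of N/2 per
arm; `simple` coin-flip allocation is available) and then assigned to J
clusters by one of four mechanisms:

* `equal` — uniform over all J therapists (assignment correlation 0);
* `partial_80_20` — therapists split into two equal sets; arm-1 patients go
  to the first set with probability 0.8, arm-0 patients with probability
  0.2 (limiting within-cluster assignment correlation 0.36);
* `one_arm` — each arm has a dedicated half of the therapists, uniform
  within it (correlation 1);
* `pre_blocks` — pre-randomisation clustering: patients arrive pre-grouped
  into equal clusters and are randomised within cluster in permuted blocks
  (correlation −1/(n−1)).

Therapist caseloads are probabilistic by default — patients are drawn to
therapists independently, so caseloads vary and a therapist can rarely be
empty; empty therapists simply contribute no fixed-effect indicator or
cluster mean, and degrees of freedom count occupied clusters. An optional
`balanced` caseload mode deals exactly N/J patients to each therapist while
honouring each mechanism's arm mixture in expectation, for designs where
caseloads are administratively fixed. Cluster effects are drawn fresh for
every replicate; there are no persistent therapist effects across replicates.

## Analyses

* **Unadjusted**: OLS of outcome on treatment; identical to the pooled
  two-sample t-test, df = N − 2.
* **Fixed effects**: OLS of outcome on treatment plus indicator variables
  for occupied clusters, df = N − J_occ − 1. Requires at least one cluster
  containing both arms; under one-arm clustering treatment is perfectly
  collinear with the indicators and a `ConfoundedDesignError` directs the
  caller to cluster summaries.
* **Cluster summaries**: each occupied cluster's unweighted mean outcome is
  regressed on the cluster's arm, df = J_occ − 2; equivalent to a two-sample
  t-test on the cluster means. Chosen over mixed models for the one-arm
  design because mixed models behave poorly with clustering nested in arms
  and few clusters per arm. Means are unweighted — each cluster counts once
  regardless of caseload — following standard cluster-trial methodology.

Zero-residual-variance inputs (possible only for degenerate hand-made data;
probability zero under the continuous generator) raise `DegenerateFitError`
rather than dividing by zero. The per-dataset estimators are statsmodels OLS
fits; the Monte-Carlo engine below recomputes the same statistics in closed
form and the test suite asserts replicate-by-replicate agreement to 1e-8.

## Monte-Carlo study

The default grid crosses ICC ∈ {0, 0.05, 0.10}, the three post-randomisation
mechanisms, and four designs (J, N) ∈ {(10, 100), (10, 200), (50, 500),
(50, 1000)} — 36 scenarios, 5000 replicates each, β = 0. Every scenario's
replicate datasets are simulated once and analysed twice: unadjusted, and
the matching adjusted analysis (fixed effects, or cluster summaries under
`one_arm`). Headline summaries average rates over the four designs at fixed
mechanism and ICC, since results are similar across designs; the pooled
"ignorable" aggregate covers the 20 scenarios with ICC 0 or equal-probability
assignment, and the adjusted aggregate is reported both over all 24 non-zero
ICC scenarios and over the 16 whose clustering is non-ignorable.

The engine vectorises whole batches of replicates: forced allocation by
rank-thresholding a uniform matrix, per-cluster sums by flat `bincount`,
fixed effects by within-cluster demeaning (algebraically identical to
indicator-variable OLS). Random streams are Philox generators keyed by
(master seed, scenario fingerprint, batch index) with a fixed batch size of
1000 replicates, so batches are independently reproducible and a study is a
pure function of its master seed regardless of grid order or parallel
scheduling. Replicates with failed fits (e.g. fewer than two occupied
clusters in an arm) are excluded from the denominator and reported; under
the default designs they are essentially absent.

`estimate_variance_decomposition` estimates V0 as the mean model-based
squared standard error across replicates and the total as the empirical
variance of β̂ across replicates, so VE = total − V0 requires no closed
form. Its sign matches the classifier's prediction: positive under one-arm
clustering, negative under pre-randomised blocks (where exact within-cluster
balance cancels the cluster effects from the arm contrast, making the true
variance 4/N against a model-based (1+σ²)·4/N). The sign tests use ICC 0.30
for the blocked design because the deflation, σ²·4/N, must dominate the
Monte-Carlo error of a variance estimate at 2000 replicates; at ICC 0.10 it
does not.

## Power loss for ignorable clustering

When clustering is ignorable the unadjusted analysis is valid but noisier:
adjustment would remove the between-cluster variance component, leaving
residual variance (1−ρ) of the total. Modelling the adjusted analysis as
powered at exactly the target (default 80%, two-sided α = 0.05) and the
unadjusted analysis as the same contrast against total variance 1, the
normal approximation gives attained power
Φ((z_{1−α/2} + z_{power})·√(1−ρ) − z_{1−α/2}), and

    loss(ρ) = target − Φ((z_{1−α/2} + z_{power})·√(1−ρ) − z_{1−α/2}),

which is 0 at ρ = 0, strictly increasing, and equals 4.3/9.3/15.0 percentage
points at ρ = 0.10/0.20/0.30.

## Scope and limitations

* Outcomes are continuous and normal; binary and time-to-event extensions
  are out of scope.
* No mixed-effects, GEE or permutation-test analyses; the three analyses
  above are the ones whose operating characteristics the study quantifies.
* Treatment-by-cluster interactions are not modelled (primary-analysis
  focus).
* The generator draws cluster effects i.i.d. normal and assigns patients to
  clusters independently of their characteristics; real trials may have
  skewed caseloads, non-normal outcomes, and cluster effects correlated with
  case mix, so nominal-rate results here demonstrate the mechanism, not a
  guarantee for any particular trial.
* VE is only ever estimated by simulation, never computed in closed form.
* The study runner executes scenarios serially; the batch-keyed random
  streams make parallel execution straightforward without changing results.

## Test strategy

Closed-form correlations, the case-study classification and estimator
algebra are checked exactly or to 1e-10 against independent oracles
(enumeration, scipy's t-test, a brute-force normal-equations solve).
Stochastic checks fix seeds and use tolerances of three Monte-Carlo standard
errors at the replication size actually run; the acceptance-style tests run
the grid at 2000 replicates per scenario, and `scripts/acceptance.py` runs
the full 5000-replicate protocol.
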