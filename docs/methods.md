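# Methods

## The problem being measured

When a prediction model for a rare (minority) class is evaluated by k-fold
cross-validation, every step that uses the data — including any rebalancing
of the class frequencies — must be confined to the training partition of
each fold.  Rebalancing the *whole* dataset first and cross-validating
afterwards lets copies of test samples reach the training set: simple
oversampling plants bitwise replicas, SMOTE plants points interpolated from
them.  A high-capacity classifier then partially memorizes the test set and
the CV estimate becomes overoptimistic.  The package quantifies this bias on
data where the truth is known by construction.

## The null simulation design

`NullDesign(n, p, minority_fraction, seed)` draws an `n × p` matrix of
i.i.d. standard-normal features and assigns exactly
`round(minority_fraction · n)` minority labels to randomly chosen rows,
independent of the features.  Defaults follow the study conditions used
throughout: 10 % minority, `p = 10`, `n ∈ {100, 1000}` in the analysis
scripts (the grid driver accepts `n` up to 10⁴ and `p = 100`).  The count
is deterministic, not binomial — the imbalance level is a design constant,
so every run probes the same regime.  Because labels are independent of
features, the population values of the measures are known: AUC = GM = 0.5,
PA_min + PA_maj = 1.  Any protocol that reports otherwise is biased.

What the generator deliberately does not emulate: feature correlation,
informative signal, heteroscedasticity, non-Gaussian marginals, missing
values.  Passing tests therefore demonstrate the *estimation* properties of
the protocols, not classifier performance on real data; the real-data runner
exists for the latter but ships with no external datasets.

## Samplers

* **Random undersampling** keeps all `n_min` minority rows plus `n_min`
  majority rows drawn without replacement (balanced output of `2·n_min`).
* **Simple oversampling** keeps all `n_maj` majority rows plus `n_maj`
  minority draws *with replacement* (balanced output of `2·n_maj`).  The
  minority originals are not additionally retained; the drawn rows are exact
  replicas and are tagged as such.
* **SMOTE** generates `percent_over/100` synthetic rows per minority sample
  `x` as `x + u·(z − x)`, `u ~ U(0,1)` drawn once per synthetic row (shared
  across features), `z` uniform over the `k = 5` nearest minority neighbours
  by Euclidean distance on the raw features (self excluded, distance ties
  broken by lowest sample index).  `percent_under/100` majority rows per
  synthetic row are retained by a draw **without** replacement, capped at
  `n_maj` with a warning.  When the minority class has fewer than `k + 1`
  members the neighbour pool shrinks to `n_min − 1` with a warning — this
  happens routinely in small training folds and is reported, not fatal.

All samplers are pure functions of `(data, seed)`.  Provenance tags
(`original`/`replica`/`synthetic`) ride along for diagnostics only.

## Classifiers

CART is the workhorse: Gini impurity, splits attempted at nodes with ≥ 2
samples, maximum depth 30, and weakest-link cost-complexity pruning with
complexity parameter `cp = 0.01` — the standard recursive-partitioning
defaults.  The tree is grown fully by scikit-learn and pruned here on the
**misclassification-risk** scale: the reported tree minimizes
`R(T) + cp · R(root) · |leaves(T)|`, so a split survives only if it buys at
least `cp · R(root)` training risk; ties collapse toward the smaller tree.
A row's score is the minority proportion of its pruned leaf.  `cp = 0`
disables pruning and recovers the interpolating tree (zero training error on
distinct points), which is the capacity ceiling for the leakage mechanism;
`cp = 1` collapses to the root.  The distribution of results under the
default was checked against an independent recursive-partitioning
implementation on the same simulation cells during development.

1-NN (score = neighbour's class) is included because it makes the leakage
argument exact: a test replica has a zero-distance training twin whenever
leakage occurs, so its minority accuracy equals the leakage probability.

Classification uses score > 0.5; a score of exactly 0.5 (perfectly mixed
leaf) goes to the majority class, a conservative and documented tie rule.

## Cross-validation

Folds are balanced: within each class, indices are shuffled and dealt
round-robin, so per-class fold sizes differ by at most one.  A class with
fewer than `k` members is an error (a fold would miss it).  In the
**correct** protocol folds are built on the original data and the sampler is
re-applied to each training partition with an independent substream; test
folds are untouched.  In the **incorrect** protocol the sampler is applied
once to the full dataset and folds are built on the resampled labels with no
awareness of replica lineage — deliberately so, since that flawed procedure
is the object of study.  Measures are computed per fold and averaged over
the k folds (AUC included); a single-class test fold would be skipped with a
warning, but balanced folds make that unreachable in every configuration
used here.  Replicated runs derive one `(data seed, protocol seed)` pair per
run from a root seed by position, so reducing the number of runs leaves the
earlier runs bit-for-bit unchanged.

## Performance measures

PA is the proportion of correct predictions; PA_min and PA_maj restrict it
to minority and majority truths; GM = √(PA_min·PA_maj); Precision is the
proportion of minority predictions that are correct; F1 is the harmonic mean
of Precision and PA_min, defined as 0 when `Precision + PA_min = 0` (this
occurs in correct-protocol null runs, where trees trained on balanced data
rarely predict minority on imbalanced test folds — visible as F1 ≈ 0.14–0.17
against ≈ 0.7 under the incorrect protocol).  AUC is the Mann–Whitney rank
statistic of the minority scores with ties counted ½ — identical to the
trapezoidal ROC area but with the tie convention explicit, which matters
because tree scores are heavily tied.

## Replica-leakage probability

For a set of `n` rows partitioned into a test part of `n·p_test` rows, where
one sample has exactly `r = n_maj/n_min` copies, the probability that a copy
sitting in the test part has another copy in the training part is

    1 − C(n−r, n·p_test−r) / C(n−1, n·p_test−1)    for n·p_test ≥ r, else 1,

computed with log-gamma arithmetic (stable to `n ≈ 10⁴`).  Two modelling
conventions deserve note, both settled empirically with the Monte-Carlo
oracle:

1. **Which `n`?**  The formula is the exact conditional probability for the
   set actually partitioned — after oversampling, `2·n_maj` rows.
   Evaluating it at the original size `n = n_min + n_maj` (as the
   illustration curve does) idealizes the split as acting on the original
   samples; at `n = 100`, half split, the two evaluations differ by < 0.001
   and both sit within Monte-Carlo error of the oracle.
2. **Exact vs multinomial replication.**  The closed form assumes each
   minority sample has exactly `r` copies.  The with-replacement draw of
   simple oversampling replicates multinomially; near balance this *adds*
   leakage (duplicates arise even at `r = 1`, where the exact model gives
   0).  The oracle therefore defaults to exact replication (the formula's
   model) and offers `replication="pipeline"` for the with-replacement
   mechanism; the pipeline estimate at a 10 % minority is lower than the
   exact value by only ~0.005.

The curve generator uses the gamma continuation of the binomial coefficients
so that non-integer replication factors produce a smooth, monotone curve;
the strict `ReplicaSpec` API refuses non-integer `r` rather than rounding.

## Numerical and design choices

* Minority class is coded 1 and is the positive class for every measure.
* Neighbour-distance ties in SMOTE break by lowest index; fold dealing and
  all draws use `numpy.random.Generator` substreams spawned per purpose
  (data, folds, per-fold samplers), so protocols are comparable run by run.
* Sampler outputs have a documented row layout (originals, then generated
  rows grouped by parent, then majority) so geometric diagnostics can
  reconstruct parentage without extra bookkeeping.
* The simulation driver writes cells incrementally with a JSON manifest of
  the grid and seed; failing cells warn and are skipped rather than aborting
  the sweep.
* Analysis scripts use 200 runs (n=1000 table) and 500 runs (n=100
  differences) per cell; at these counts the Monte-Carlo SE of a mean AUC is
  ≈ 0.001–0.002, an order of magnitude below the effects of interest.  The
  full 1000-run grid is available through `SimulationGrid(runs=1000)` or
  `imbcv simulate`.

## Expression-matrix preprocessing

The real-data path implements the two filters commonly applied to two-channel
microarray matrices: drop features with > 10 % missing values, replace the
remaining gaps with zeros, and keep the 1000 highest-variance features.
Multi-class labels are binarized by declaring one value the minority class.
No dataset-specific normalization is attempted.

## Known limitations

* The incorrect-protocol bias magnitudes depend on the classifier's
  regularization; they are reproducible for the CART defaults above but will
  differ for other `cp`, depth, or learners (the knobs are exposed).
* SMOTE follows the canonical algorithm; implementations differ in minor
  conventions (majority retention with vs without replacement, per-feature
  vs per-row interpolation coefficients), which shift the biased estimates
  by a few hundredths of AUC without changing any qualitative conclusion.
* The closed form covers replica leakage from simple oversampling only;
  SMOTE leakage has no closed form here and is demonstrated empirically.
* `run_real_data_study` re-randomizes folds and samplers on a fixed dataset,
  so its SEs reflect CV noise, not sampling variability of the data.
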