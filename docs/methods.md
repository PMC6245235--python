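# Methods

## The model

`nearestcc` implements a cluster-then-classify strategy for disease
subtyping on tabular patient cohorts. The premise: a heterogeneous disease
hides subgroups whose outcome-relevant physiology differs, so one global
classifier trained on the pooled cohort averages over contradictory
decision rules. The pipeline therefore

1. **discovers subgroups by consensus clustering.** The standardized
   training features are resampled B times (default B = 10, 80% subsamples
   without replacement) and K-means is run on each resample. An n × n
   *agreement matrix* accumulates, for each pair of patients, the number of
   resamples in which both were drawn (`co_present`) and the number in
   which they additionally shared a cluster (`co_cluster`). The consensus
   step runs K-means on the rows of the normalized matrix
   `ratio = co_cluster / co_present` — each patient's co-clustering profile
   is their feature vector — yielding one partition of the full training
   set. Normalizing by co-presence stops subsampling from penalizing pairs
   that were rarely drawn together; the raw counts are available by flag.
2. **trains one decision tree per consensus cluster.** Trees use the
   C4.5 split criterion (gain ratio = information gain / split
   information), binary splits at midpoints between consecutive distinct
   feature values, ties broken to the lowest feature index then lowest
   threshold. A cluster below `min_cluster_size` (default 10) rows carries
   no tree and defers to a fallback tree trained on all training rows.
3. **routes a new patient to the linkage-nearest cluster** in the
   standardized feature space — single (nearest member), complete
   (farthest member), or average linkage over Euclidean distances — and
   classifies with that cluster's tree. Routing happens in data space
   because a new patient has no row in the agreement matrix.

Baselines behind the same interface: a single global tree (no clustering),
"nearest K-means" (one K-means partition, no resampling/consensus),
analogues using agglomerative clustering and PAM, and SVM variants
(scikit-learn's SVC globally or per K-means cluster).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | cluster count, used both for input clusterings and consensus |
| `b` | 10 | number of resampled input clusterings |
| `fraction` | 0.8 | resample size as a fraction of training rows (without replacement; bootstrap by flag) |
| `linkage` | single | point-to-cluster distance for routing |
| `min_cluster_size` | 10 | below this a cluster defers to the fallback tree |
| `restarts` | 10 | K-means restarts (distance-weighted seeding) |
| `input_restarts` | = restarts | restarts for the data-space input clusterings only |
| `tree_max_depth` | 4 | tree depth bound (no C4.5 post-pruning is applied) |
| `tree_min_leaf` / `tree_min_split` | 5 / 10 | minimum child / node size for a split |
| threshold | 60 months | time-to-event cut defining class "1" (event within) vs "2" |

The bare `fit_tree` function keeps the looser conventional defaults
(`min_leaf=2`, `min_split=4`, unlimited depth); the pipeline bounds tree
growth because no pessimistic pruning is implemented and unbounded greedy
trees memorize their training split.

Standardization uses the training mean and sample standard deviation
(ddof = 1); constant features map to 0; binary features pass through
unchanged. Imputation (median for continuous, mode with ties-to-0 for
binary) always uses training-side statistics; the fitted model carries its
imputer so evaluation splits cannot leak test information.

Cohorts with survival columns are labeled by a threshold (default 60
months): event within the threshold (inclusive) → class "1"; followed past
the threshold without the event by then → class "2"; censored before the
threshold → excluded, since the class of such a patient is unknowable.

## Synthetic cohorts

The generator plants `g` subgroups in an SSc-registry-shaped table:
5 continuous labs (hemoglobin, creatinine, FVC, DLCO, age at onset),
8 binary antibody flags, a two-valued outcome class, and months-to-event
columns with an event/censoring flag.

- **Separation.** Subgroup centers differ on creatinine, DLCO and age,
  placed on an equilateral geometry with pairwise spacing of 1.5 pooled
  standard deviations, scaled by the `separation` multiplier; the antibody
  profiles acquire subgroup-specific signatures scaled the same way. At
  the reference multiplier 6 the centers sit ~9 sds apart, so boundary
  misassignment is negligible (per-point error ≈ 2Φ(−4.5)) and planted
  recovery should be essentially exact; at multiplier 0 every subgroup is
  identically distributed and any recovery is chance. The
  method-comparison experiments use multiplier 3 (~4.5 sds): a partially
  overlapping regime in which clustering is good but fallible, which is
  the regime the method targets.
- **Contradictory outcome rules.** All three class rules key on
  hemoglobin, which is identically distributed in every subgroup (it
  carries no clustering signal): class "1" below 11.85 g/dL in subgroup 0,
  *above* 12.6 in subgroup 1, below 14.1 in subgroup 2. Any single
  subgroup's rule is therefore actively wrong — not merely uninformative —
  on the other subgroups, which is the minimal structure under which a
  lone cluster's model must transfer badly while per-cluster models
  excel. Labels are flipped with probability `label_noise` (default 0.03;
  0.08 in the comparison conditions).
- **Survival.** Event times are exponential with per-subgroup monthly
  rates (0.012, 0.005, 0.002), censored by an independent uniform horizon
  on (0, 180) months. The memoryless choice keeps every survival quantity
  available in closed form; Weibull shapes are out of scope. The planted
  hazard ordering should reappear as ordered per-cluster Kaplan-Meier
  curves (survival at 120 months ≈ 0.24 / 0.55 / 0.79).

What the generator does *not* emulate: real SSc marginals or antibody
co-occurrence, correlated features within a subgroup, informative
censoring, and non-Gaussian lab distributions. Tests passing on these
cohorts show the machinery is correct and that the method's claimed
advantages appear when its assumptions hold — not that they will appear
on any particular clinical dataset.

## Evaluation protocol

Repeated holdout (default 10 repeats, 80/20) with class-stratified splits:
ten unstratified 20% draws on imbalanced clinical data can lose a class
entirely, and stratification keeps every method comparable within a
repeat (all methods see identical splits). Per-cluster diagnostic entries
(`method:clusterJ`) score each cluster's own tree alone on the full test
set; clusters that deferred to the fallback are skipped since they carry
no model of their own. Error distributions are compared with Welch's
unequal-variance t-test (two-sided; a paired variant is available by
flag). The K sweep re-runs the protocol across a cluster-count grid
(default {3, 4, 5, 7, 10}). Kaplan-Meier curves use the product-limit
estimator; censored rows shrink later risk sets without producing a step.

The comparison experiments run the input clusterings with a single
restart (`comparison_config()`): the contrast under study is exactly the
run-to-run and sampling variability of K-means that the consensus is
designed to absorb, and a best-of-10 restart search on every input
clustering would already be a miniature consensus. The consensus-
extraction K-means keeps its full restart budget.

### A negative result worth knowing

Under this generator the consensus classifier is consistently *at least
as good as* nearest K-means, but the improvement is rarely statistically
significant in an unpaired t-test over 10 repeats. The reason is
structural: with distance-weighted seeding and spherical subgroups, a
single K-means run recovers the partition almost as well as the
consensus; nearest K-means fails only in occasional repeats (a bad local
optimum), producing a rare-event error mixture that a two-sample t-test
at n = 10 cannot resolve. Regimes engineered to make single runs fail
often (strong cluster-size imbalance) make the failure systematic — every
run merges the same two small subgroups — so the consensus inherits the
error instead of repairing it. The acceptance suite keeps the
significance check at its stated threshold and it fails honestly;
consensus clustering's practical value here is stability, and on cleanly
spherical synthetic subgroups stability is cheap.

## Numerical conventions

- A feature value exactly equal to a split threshold descends left
  (≤ convention); events exactly at the labeling threshold count as
  "within".
- Leaf predictions are the majority label, ties to the lexicographically
  smallest label; nearest-centroid/medoid and routing ties go to the
  lowest cluster index.
- Empty K-means clusters are repaired by reseeding the empty centroid at
  the point farthest from its current centroid; within a restart the SSE
  is non-increasing and iteration stops when its decrease falls below
  `tol` (1e-6).
- PAM is a multi-start local search: greedy BUILD plus random initial
  medoid sets (default 5 starts), best-improvement single swaps until no
  swap improves. Single-start single-swap search demonstrably stalls
  above the optimum on a few percent of even 7-point instances.
- Agreement ratios are 0 for pairs never jointly sampled (no evidence ≠
  evidence of disagreement), and 1 on the diagonal for any item drawn at
  least once.
- Cluster labels are nominal, so partition agreement aligns labels by
  maximum-overlap assignment (Hungarian algorithm on the contingency
  table) before computing Cohen's kappa; the kappa is unweighted because
  nominal clusters have no order to weight by.
- All randomness flows from one master seed through named substreams
  (label-hashed `SeedSequence`), so identical configurations reproduce
  models and result files byte for byte.

## Known limitations

- No C4.5 pessimistic pruning or fractional handling of missing values at
  prediction time; the stopping rules substitute for pruning.
- Consensus extraction is K-means on agreement profiles; spectral or
  hierarchical consensus extraction is out of scope, as is consensus
  across different algorithm families.
- The SVM baselines delegate to scikit-learn and have no text snapshot
  serialization.
- `kappa_agreement` measures nominal partition agreement only; with very
  unequal cluster counts the unmatched clusters are treated as fresh
  labels, which deflates agreement by design.
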