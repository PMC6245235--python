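# nearestcc

Nearest consensus clustering classification: simultaneous patient
subgroup discovery and per-subgroup outcome prediction for tabular
clinical cohorts.

Heterogeneous diseases such as systemic sclerosis hide subgroups whose
prognosis-relevant physiology differs, so a single classifier trained on
the pooled cohort averages over contradictory decision rules. This
package trains K-means on repeated resamples of the training cohort,
combines the runs into an n × n **agreement matrix** A where
A<sub>ij</sub> counts how often patients i and j co-cluster (normalized
by how often they were jointly sampled), extracts **consensus clusters**
by clustering the rows of A, grows one **gain-ratio (C4.5-style) decision
tree per cluster**, and classifies a new patient with the tree of their
**linkage-nearest cluster** (single, complete, or average linkage under
Euclidean distance):

- consensus: K-means over rows of `ratio(i,j) = co_cluster(i,j) / co_present(i,j)`
- trees: split maximizing `gain_ratio = [H(parent) − Σ (nᵢ/n) H(childᵢ)] / split_info`
- routing: `argmin_c linkage(x, cluster_c)`, then predict with tree<sub>c</sub>

Alongside the classifier: baselines (global tree, nearest K-means,
PAM / hierarchical variants, SVMs), a repeated-stratified-holdout
evaluation harness with Welch t-tests and a K sweep, per-cluster
Kaplan-Meier survival curves, time-to-event labeling (event within 60
months → class "1", followed past it → class "2", censored early →
excluded), and a synthetic cohort generator with planted subgroups,
contradictory per-subgroup outcome rules, and subgroup-specific
exponential hazards. See `docs/methods.md` for the full model
description.

## Worked example

```python
import nearestcc as ncc

# a 600-patient synthetic cohort: 3 planted subgroups, contradictory
# hemoglobin rules, subgroup-specific survival
table, truth = ncc.generate_cohort(ncc.default_ssc_like_spec(), rng=1)

model = ncc.fit_nearest_cc(table, ncc.NearestCCConfig(k=3, seed=1))
print([c.size for c in model.clusters])
# [201, 149, 250]

pred = ncc.predict_nearest_cc(model, table)
print((pred == table.y).mean())
# 0.975

curves = ncc.km_by_cluster(model, table)
print({lab: round(c.survival_at(120.0), 2) for lab, c in curves.items()})
# {0: 0.52, 1: 0.79, 2: 0.19}
```

The three consensus clusters recover the planted subgroups — sizes 250,
201, 149 against the 0.40/0.35/0.25 mixing weights at n = 600 (cluster
labels are arbitrary) — and the per-cluster trees classify 97.5% of
patients correctly despite outcome rules that contradict each other
across subgroups. The per-cluster Kaplan-Meier survival at 120 months
(0.19, 0.52, 0.79 after sorting) reproduces the planted hazard ordering
of the three subgroups.

The same pipeline is scriptable from the shell:

```sh
nearest-cc simulate --n 600 --seed 1 --out run/sim
nearest-cc evaluate --data run/sim/cohort.csv --schema run/sim/schema.yaml \
    --method nearest-cc --method global-tree --out run/eval
nearest-cc km --data run/sim/cohort.csv --schema run/sim/schema.yaml --out run/km
```

Each command writes tidy CSVs plus a resolved-config JSON; identical
configurations reproduce outputs byte for byte.

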