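# fcsubtypes

Linking resting-state functional connectivity (FC) to neuropsychiatric
symptoms (NPS) with sparse canonical correlation analysis, and
subtyping participants in the resulting latent plane.

## The problem

Neuropsychiatric symptoms in dementia are heterogeneous: two patients
with the same diagnosis can differ completely in agitation, anxiety,
apathy or sleep disturbance, and case–control averages wash that
structure out. This package implements a data-driven framework for
researchers who have, per participant, a parcellated resting-state
connectome (edge vector of pairwise Pearson correlations) and the 12
ordinal Neuropsychiatric Inventory domain scores (0–3), and who want
to:

1. find paired latent dimensions ("subsyndromes") along which FC and
   symptoms covary,
2. cluster participants into neurophysiological subtypes in the FC
   latent plane, with honest stability diagnostics, and
3. transfer the frozen model to a replication cohort.

## The model

With column-standardized views `X` (n×p edges) and `Y` (n×q symptom
principal components), each canonical component solves the penalized
matrix decomposition

    max  uᵀXᵀYv   s.t.  ‖u‖₂≤1, ‖v‖₂≤1, ‖u‖₁≤c₁·√p, ‖v‖₁≤c₂·√q

by alternating closed-form soft-threshold updates, with rank-1
deflation for later components. Hyperparameters (penalty, number of
symptom PCs) are chosen by the mean held-out correlation of paired
variates in 10-fold cross-validation; significance comes from a
permutation test (shuffle one view's rows, refit, add-one one-sided p)
with Benjamini–Hochberg FDR. Subtypes are k-means clusters of the 2-D
FC latent scores, screened by Silhouette/Calinski–Harabasz over 1000
random 90% subsamples, with per-participant reassignment-instability
flags (>5% rule) and a Ward-linkage cross-check. Post hoc tools cover
edge/symptom loadings, 7-network contribution grids, per-edge rank-sum
group tests with FDR, Kruskal–Wallis/Dunn phenotype comparisons, and
longitudinal linear mixed-effects progression models. See
`docs/methods.md` for the full account.

Real cohorts of this kind are access-controlled, so the package ships a
first-class synthetic-data module that plants exactly the structure the
analysis assumes — sparse canonical cross-covariance, ordinal symptom
scores, a 3-component subtype mixture, subtype-specific longitudinal
slopes — and every benchmark runs against that ground truth.

## Worked example

```python
import numpy as np
from fcsubtypes import (
    GeneratorConfig, SCCAHyperparams, generate_cohort,
    cv_select, fit_latent, fit_kmeans, assignment_stability, select_k,
)
from fcsubtypes.latent import support_recovery

# A discovery cohort: 300 participants, 100 ROIs (4950 edges),
# two planted subsyndromes of strength 0.6 and 0.4, three subtypes.
cohort = generate_cohort(GeneratorConfig(n_participants=300, seed=11))

cv = cv_select(cohort.edges, cohort.nps,
               n_pcs_grid=(7,), penalty_grid=(0.6,), n_folds=10, seed=0)
print("held-out canonical r:",
      round(float(cv.means[cv.means.component == 1].mean_r.iloc[0]), 3))

model = fit_latent(cohort.edges, cohort.nps,
                   SCCAHyperparams(0.6, 0.6, n_components=2, n_pcs=7))
recall, precision = support_recovery(model.scca.u[:, 0],
                                     cohort.true_edge_weights[0])
print("planted-edge recovery: recall", recall, "precision", precision)

# Subtype the latent plane and check stability.
scores = cohort.true_latent
ksel = select_k(scores, n_trials=200, seed=0)
km = fit_kmeans(scores, 3, seed=0)
stab = assignment_stability(scores, km, n_trials=500, seed=0)
print("recommended k:", ksel.recommended_k,
      "| unstable participants:", int(stab.unstable.sum()), "/ 300")
```

prints

```
held-out canonical r: 0.464
planted-edge recovery: recall 1.0 precision 1.0
recommended k: 3 | unstable participants: 1 / 300
```

The held-out correlation of ~0.46 is the cross-view canonical
correlation the model actually generalizes at (the planted FC-side
strength is 0.6; symptom discretization and estimation noise account
for the gap). All ten planted edges are found, the subsample screen
recommends the planted three clusters, and only a few participants near
cluster boundaries are flagged as unstable under 90% subsampling.

The same workflow is available from the shell:

```sh
fcsubtypes simulate --seed 1 --out cohort/
fcsubtypes run-all --config config.yaml --seed 1 --out results/
fcsubtypes replicate --config rep.yaml --discovery results/ --out rep_results/
```

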