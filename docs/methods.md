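# Methods

`fcsubtypes` implements a data-driven framework that links resting-state
functional connectivity (FC) to neuropsychiatric symptoms (NPS), derives
low-dimensional *subsyndrome* axes, clusters participants into
neurophysiological subtypes in the resulting latent plane, and transfers
the frozen model to a replication cohort. This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Connectome representation

A participant's parcellated BOLD signal (100 cortical regions by
default, Schaefer-style) is reduced to the Pearson correlation matrix of
the region time series. The strictly-upper triangle in row-major order
— 4950 edges for 100 regions — is the canonical feature vector;
`vectorize`/`devectorize` are exact inverses so every table and weight
vector shares one edge order. Edges are used as raw correlations by
default; an optional Fisher z transform is exposed (`fisher_z` flag) but
off, since the analysis is defined on plain Pearson FC. Ingested
matrices must be symmetric within 1e-10. Region-to-network lookups use
a packaged 100-region, 7-network table (VIS, SMN, DAN, VAN, LIM, FPC,
DMN); the packaged file is a stylized, synthetic assignment with
realistic network sizes, not a redistribution of any atlas.

## Latent model

**Symptom PCA.** The 12 ordinal NPS domain scores (0–3) are strongly
collinear, so they are first decorrelated by PCA. The component count is
either fixed (the pipeline default is 7) or chosen as the smallest count
explaining >80% variance. Missing domain scores are imputed as 0
(symptom absent) by default — consistent with an inclusion rule that
requires at least one recorded symptom — with per-run counts logged;
median imputation is available.

**Sparse CCA as penalized matrix decomposition.** With standardized
views X (n×p edges) and Y (n×q symptom PCs), each component solves

    max u'X'Yv   s.t. ||u||2<=1, ||v||2<=1, ||u||1<=c1, ||v||1<=c2

with c1 = penalty_x·sqrt(p), c2 = penalty_y·sqrt(q) and penalties in
(0,1]. This diagonal-penalized formulation treats within-view
covariance as identity, the standard simplification when p≫n. The
alternating update for each block is available in closed form
(soft-threshold, then L2-normalize); the active threshold is found
exactly by solving a per-segment quadratic on the sorted-magnitude path,
with a bisection fallback for degenerate segments. Iteration starts from
the leading right singular vector (deterministic) and stops when both
weight vectors change by less than 1e-9 (max 1000 iterations;
non-convergence is flagged on the model, not raised). Later components
come from rank-1 deflation of the cross-product. With penalties at 1 the
solution equals the leading singular triplet, which is tested to 1e-6.

Both views are z-scored with the sample SD (ddof=1); the standardization
is stored on the model so the frozen transform is exact. Components are
sign-oriented so the largest-magnitude symptom-side weight is positive
(canonical pairs are sign-indeterminate; the flip is recorded). The
covariance-explained fraction of component k is d_k over the sum of the
fitted singular values.

**Hyperparameter selection.** A grid over {number of PCs} × {penalty}
is scored by the mean Pearson correlation of paired held-out variates in
10-fold CV. Strict hygiene: imputation, PCA, standardization and the
sparse CCA are all refit inside every training fold; held-out rows are
only transformed. This is verified by corrupting a held-out fold and
checking the fold's fitted weights are bit-identical. Ties break toward
the smaller penalty, then fewer PCs.

**Permutation inference.** Significance of each canonical correlation
comes from shuffling participant rows of the symptom view and refitting
the model, with one-sided add-one p-values, p = (1+#{null≥obs})/(1+B),
and Benjamini–Hochberg FDR across components. The recorded statistic is
configurable:

* `cv` (default): the mean held-out correlation over k folds, for both
  the observed and every permuted refit. With p≫n an unrestricted refit
  overfits a shuffled cohort as easily as the real one — measured
  in-sample null correlations (~0.97) *exceed* the observed fit's
  (~0.94) at n=300, p=4950 — so in-sample correlation has no power; the
  held-out statistic restores it and matches how model performance is
  reported.
* `insample_r`: the in-sample canonical correlation of a single full
  refit per permutation. Cheap, exchangeable, and exactly calibrated
  under the null; used where only type-I control matters.

## Subtyping

Participants (patients and controls together, by default; a
patients-only flag exists) are clustered by k-means on the first two
FC-side latent scores. The pipeline's headline k is 3, but a screen over
k=2..6 always runs: 1000 random 90% subsamples, each scored by
Silhouette and Calinski–Harabasz; the recommendation maximizes the
median Silhouette with median CH as tie-break, and a run where every k
has median Silhouette below 0.4 is flagged "weak structure".

Assignment stability refits k-means on each subsample and maps the
trial clusters to the full-data reference by optimal one-to-one
(Hungarian) centroid matching — this also resolves the ambiguous case
of two trial centroids nearest the same reference. A participant's
instability is the fraction of its appearances with a non-reference
label; instability above 5% flags the participant. Pairwise
co-clustering consistency against the reference is reported alongside.
Ward-linkage hierarchical clustering cut at k provides a structural
cross-check (adjusted Rand index vs the k-means labels).

Replication transfer freezes everything: the PCA, the sparse CCA
weights and standardization, and the discovery centroids, which seed a
single k-means run on the replication scores (initial nearest-centroid
labels are reported too, and empty clusters are surfaced, never
dropped).

## Post hoc characterization

Edge loadings are per-edge Pearson correlations with an FC latent
score; symptom loadings are per-domain Spearman correlations (midrank
ties). Any per-edge quantity can be aggregated into a 7×7 network grid
by summing absolute values over edges grouped by their endpoint
networks; the grid total equals the sum of |value| over all unmasked
edges exactly. Two-group edge comparisons use the Wilcoxon rank-sum
test in a vectorized normal approximation with midranks and tie
correction (no continuity correction; verified against exact
enumeration on 4-vs-4 inputs), BH-FDR across edges, and network sums of
|z| restricted to FDR-surviving edges. Phenotypes across subtypes are
compared by chi-square (categorical; expected counts below 1 attach a
warning) or Kruskal–Wallis with BH-corrected pairwise Dunn z tests
(ordinal/continuous), reporting per-group medians and IQRs.
Longitudinal progression uses a linear mixed-effects model,
value ~ subtype + time + subtype:time, with a random intercept per
participant, maximum-likelihood fit, subtype 3 as the reference level,
and a joint Wald F test for the interaction. The random-effects
structure (intercept only) is the package's choice; with zero
between-participant variance the fixed effects reduce to OLS, which is
tested.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, so
every stage has ground truth:

* **Latent subsyndrome severities** z per participant from a 3-component
  Gaussian mixture in the 2-D latent plane. Defaults: centroids (4,0),
  (0,4), (0,0) with unit within-cluster SD — two symptomatic subtypes
  displaced along one axis each and one mild subtype at the origin,
  adjacent centroids 4 SD apart — and mixing proportions
  (0.29, 0.28, 0.43), mirroring a 45/43/66-sized cohort split.
* **Edges**: 10 support edges per latent dimension (disjoint supports)
  carry a calibrated loading on z_k; all other edges are noise.
  `canonical_strength` (defaults 0.6, 0.4) is defined as the population
  correlation between z_k and the projection of the edge view onto the
  true unit-norm weight vector, and the loading amplitude is solved from
  the mixture variance so this holds exactly. Support-edge residuals
  share a dimension-wide common factor (`shared_noise_frac`=0.9,
  mimicking the spatially structured residual fluctuations of real FC);
  without it, per-edge signal at an aggregate strength of 0.6 would be
  too weak (≈0.23 per edge) for any sparse method to locate 10 edges
  among 4950.
* **Symptoms**: 4 support domains per dimension load on z_k at high
  fidelity (`nps_strength`=0.95) before discretization to 0–3 by fixed
  global thresholds (0.8, 1.8, 2.8), mimicking an instrument with fixed
  anchors. Symptoms define the latent severity; connectivity reflects
  it at `canonical_strength` — so the cross-view canonical correlation
  is approximately `canonical_strength` itself rather than its square.
* **Longitudinal decline**: value(i,t) = intercept_i + slope(subtype)·t
  + noise on a fixed visit grid (4 annual visits), random intercepts
  SD 0.3, residual SD 0.12, subtype slopes (0.05, 0.05, 0.0) per visit —
  the effect size matching the scale of reported cognitive-subscore
  drift, with noise at a level a short clinical subscore plausibly
  shows.
* A replication cohort is drawn with `replicate_seed`: same planted
  structure, fresh participants.
* An optional time-series path generates ROI×time Gaussian series with
  a prescribed population correlation, so the connectome stage is
  exercised end to end.

**What the generator does not emulate:** hemodynamics and scanner
noise, site/batch effects, motion artifacts, non-Gaussian edge
distributions, missing-visit patterns, and any coupling between
diagnosis and FC beyond the planted latent structure (the stylized
clinical covariates exist only to exercise the post hoc interfaces).
Passing recovery benchmarks therefore demonstrates the statistical
machinery is correct and calibrated under the assumed model — not that
the pipeline will find this structure in any particular real cohort.

**Support recovery metric.** At PMA-scaled penalties the L1 bound is
saturated, so hundreds of coordinates carry tiny nonzero weights; raw
nonzero-pattern precision is therefore uninformative. Recovered support
is defined as the s largest-magnitude fitted coordinates, s the true
support size (the usual top-k convention in sparse recovery); the raw
nonzero rule remains available.

## Seeds and determinism

Every stochastic routine takes a seed. The pipeline derives per-stage
seeds from one master seed through `numpy.random.SeedSequence` in a
fixed stage order (cohort, CV, permutation, k-selection, clustering,
stability), so stages are independently reproducible and a rerun under
the same master seed produces byte-identical reports and models (the
log carries the only timestamps).

## Benchmark problem sizes

The recovery benchmarks run at the study's natural scale where that is
cheap (n=300 participants, 100 ROIs / 4950 edges, 10-fold CV;
null-calibration studies at 200 datasets × 200 permutations, 500
simulated two-group cohorts, 100 mixed-model simulations) and use
latent-plane mixtures of n=150–193 for the clustering and transfer
benchmarks, matching the discovery/replication cohort sizes of the
motivating study design.

## Known limitations

* Components beyond the second depend on the deflation scheme
  (cross-product rank-1 subtraction) and are not interpreted.
* The covariance-explained fractions of a K-component fit are nearly
  flat on high-dimensional synthetic nulls because penalized refits of
  the deflated residual retain large objectives at p≫n; concentrated
  fractions arise only when the data have genuinely low-rank
  cross-covariance.
* The in-sample permutation statistic, while exactly calibrated, has
  essentially no power at p≫n; use the CV statistic for inference.
* Cluster recovery is capped by intrinsic component overlap: with
  unit-SD isotropic clusters whose adjacent centroids are 4 SD apart,
  about 3–4% of points sit on the wrong side of a boundary, so the
  expected k-means-vs-truth ARI is ≈0.89 and Ward-vs-k-means agreement
  ≈0.88 (each measured over 200 replicate cohorts at n=150). Agreement
  is a robustness indicator, not a fixed pass mark.
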