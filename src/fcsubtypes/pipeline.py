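"""End-to-end discovery -> replication orchestration.

`run_discovery` executes the full sequence — data loading (or synthetic
simulation), optional Fisher z, CV hyperparameter selection, the sparse
CCA fit, permutation inference, subtype clustering with stability
diagnostics, and post hoc characterization — from one `RunConfig`, and
writes models, tables and a machine-readable `report.json` under the
output directory.  `run_replication` applies a frozen discovery model
(no refitting) to a new cohort and clusters it from the discovery
centroids.

Randomness: one master seed fans out to per-stage seeds through
`numpy.random.SeedSequence(master).generate_state(...)`; the stage order
is fixed (cohort, CV, permutation, k-selection, clustering, stability),
so any stage can be rerun in isolation reproducibly and a rerun of the
whole pipeline under the same seed is byte-identical apart from the
timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome, latent, posthoc, subtyping
from .connectome import EdgeVector, NetworkAtlas, default_atlas, edge_columns, fisher_z as _fisher_z
from .latent import LatentModel, SCCAHyperparams
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "run_discovery", "run_replication", "stage_seeds"]

logger = logging.getLogger("fcsubtypes")

_STAGES = ("cohort", "cv", "permutation", "k_selection", "clustering", "stability")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {name: int(s % (2**31 - 1)) for name, s in zip(_STAGES, state)}


@dataclass
class RunConfig:
    """Everything one discovery (or replication) run needs."""

    # inputs: file paths, or a generator config when simulating
    edges_path: str | None = None
    nps_path: str | None = None
    longitudinal_path: str | None = None
    atlas_path: str | None = None
    generator: GeneratorConfig | None = None

    # latent stage
    n_pcs_grid: tuple[int, ...] = (5, 6, 7, 8)
    penalty_grid: tuple[float, ...] = (0.4, 0.6, 0.8)
    n_folds: int = 10
    n_components: int = 2
    n_perm: int = 1000
    perm_statistic: str = "cv"
    perm_cv_folds: int = 5

    # subtyping stage
    k: int = 3
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_trials: int = 1000
    frac: float = 0.9

    # flags
    fisher_z: bool = False
    standardize_latent: bool = False
    patients_only_clustering: bool = False
    imputation: str = "zero"

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gen = doc.pop("generator", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in doc.items()})
        if gen is not None:
            gen = {k: tuple(tuple(x) if isinstance(x, list) else x
                            for x in v) if isinstance(v, list) else v
                   for k, v in gen.items()}
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def validate(self) -> None:
        if self.generator is None:
            for name in ("edges_path", "nps_path"):
                p = getattr(self, name)
                if p is None:
                    raise FileNotFoundError(
                        f"{name} is required when no generator is configured"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p}")
        for name in ("longitudinal_path", "atlas_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p}")


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _load_inputs(config: RunConfig, seed: int):
    """Resolve the cohort: read files, or simulate from the generator."""
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=seed)
        cohort = generate_cohort(gen)
        return (cohort.edges, cohort.nps, cohort.phenotype,
                cohort.longitudinal, cohort)
    _, edges = connectome.read_edge_table(config.edges_path)
    nps_df = pd.read_csv(config.nps_path)
    nps = nps_df.drop(columns=["participant_id"], errors="ignore").to_numpy(float)
    longitudinal = (
        pd.read_csv(config.longitudinal_path)
        if config.longitudinal_path else None
    )
    return edges, nps, None, longitudinal, None


def _resolve_atlas(config: RunConfig, n_edge_cols: int) -> NetworkAtlas | None:
    if config.atlas_path is not None:
        return connectome.load_atlas(config.atlas_path)
    if n_edge_cols == connectome.n_edges(100):
        return default_atlas()
    return None


def run_discovery(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the discovery pipeline; returns the report dictionary.

    Artifacts under ``out_dir``: ``models/latent_model.json``,
    ``models/subtypes.json``, ``tables/*.csv``, ``report.json`` and
    ``log.txt``.  Any stage failure halts the run with the stage name;
    the partial report written so far is preserved.
    """
    config.validate()
    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}")

    seeds = stage_seeds(config.seed)
    report: dict = {
        "package": "fcsubtypes",
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": seeds,
        "stages": {},
        "warnings": [],
    }
    stage = "inputs"
    try:
        log("loading inputs")
        edges, nps, phenotype, longitudinal, cohort = _load_inputs(
            config, seeds["cohort"]
        )
        if config.fisher_z:
            r = int(round((1 + np.sqrt(1 + 8 * edges.shape[1])) / 2))
            edges = np.vstack([
                _fisher_z(EdgeVector(values=row, n_rois=r)).values
                for row in edges
            ])
        atlas = _resolve_atlas(config, edges.shape[1])
        report["stages"]["inputs"] = {
            "n_participants": int(edges.shape[0]),
            "n_edges": int(edges.shape[1]),
            "n_nps_domains": int(nps.shape[1]),
            "simulated": cohort is not None,
        }

        stage = "cv"
        log("cross-validated hyperparameter selection")
        cv = latent.cv_select(
            edges, nps,
            n_pcs_grid=config.n_pcs_grid, penalty_grid=config.penalty_grid,
            n_folds=config.n_folds, imputation=config.imputation,
            seed=seeds["cv"],
        )
        cv.means.to_csv(out / "tables" / "cv_means.csv", index=False)
        best1 = cv.means[
            (cv.means["n_pcs"] == cv.best_n_pcs)
            & (cv.means["penalty"] == cv.best_penalty)
            & (cv.means["component"] == 1)
        ]["mean_r"].iloc[0]
        report["stages"]["cv"] = {
            "best_n_pcs": cv.best_n_pcs,
            "best_penalty": cv.best_penalty,
            "mean_test_r_component1": float(best1),
        }

        stage = "latent"
        log("fitting the frozen PCA + sparse CCA transform")
        hp = SCCAHyperparams(
            penalty_x=cv.best_penalty, penalty_y=cv.best_penalty,
            n_components=config.n_components, n_pcs=cv.best_n_pcs,
        )
        model = latent.fit_latent(edges, nps, hp, imputation=config.imputation)
        _atomic_write(out / "models" / "latent_model.json", model.to_json())
        fc_scores, nps_scores = model.transform(edges, nps)
        report["stages"]["latent"] = {
            "canonical_r": model.scca.r.tolist(),
            "covariance_explained": model.scca.cov_explained.tolist(),
            "converged": model.scca.converged.tolist(),
        }

        stage = "permutation"
        log(f"permutation test ({config.n_perm} shuffles)")
        nps_filled, _ = latent.impute_nps(nps, config.imputation)
        pcs = model.pca.transform(nps_filled)
        perm = latent.permutation_test(
            edges, pcs, hp, n_perm=config.n_perm, seed=seeds["permutation"],
            statistic=config.perm_statistic, cv_folds=config.perm_cv_folds,
        )
        report["stages"]["permutation"] = {
            "observed_r": perm.observed_r.tolist(),
            "p": perm.p.tolist(),
            "q": perm.q.tolist(),
        }

        stage = "clustering"
        scores = fc_scores[:, :2]
        if config.standardize_latent:
            scores = (scores - scores.mean(0)) / scores.std(0, ddof=1)
        cluster_rows = np.arange(scores.shape[0])
        if config.patients_only_clustering and phenotype is not None:
            cluster_rows = np.flatnonzero(phenotype["diagnosis"].to_numpy() == 1)
        cscores = scores[cluster_rows]
        log("k selection over subsamples")
        ksel = subtyping.select_k(
            cscores, k_range=list(config.k_range),
            n_trials=config.n_trials, frac=config.frac,
            seed=seeds["k_selection"],
        )
        report["stages"]["k_selection"] = {
            "recommended_k": ksel.recommended_k,
            "weak_structure": ksel.weak_structure,
            "median_metrics": ksel.median_table().to_dict("records"),
        }
        log(f"k-means at k={config.k} plus stability")
        subtypes = subtyping.fit_kmeans(
            cscores, config.k, seed=seeds["clustering"]
        )
        stability = subtyping.assignment_stability(
            cscores, subtypes, n_trials=config.n_trials,
            frac=config.frac, seed=seeds["stability"],
        )
        ward_labels, ward_ari = subtyping.ward_check(
            cscores, config.k, subtypes.labels
        )
        labels_df = pd.DataFrame(
            {
                "row": cluster_rows,
                "subtype": subtypes.labels + 1,
                "instability": stability.instability,
                "flagged": stability.unstable,
            }
        )
        labels_df.to_csv(out / "tables" / "subtype_labels.csv", index=False)
        _atomic_write(
            out / "models" / "subtypes.json",
            json.dumps(
                {"k": subtypes.k, "centroids": subtypes.centroids.tolist(),
                 "inertia": subtypes.inertia,
                 "standardize_latent": config.standardize_latent},
                indent=1, sort_keys=True,
            ),
        )
        report["stages"]["clustering"] = {
            "k": subtypes.k,
            "sizes": np.bincount(subtypes.labels, minlength=config.k).tolist(),
            "n_flagged_unstable": int(stability.unstable.sum()),
            "ward_agreement_ari": ward_ari,
        }

        stage = "posthoc"
        log("post hoc characterization")
        names = (edge_columns(100)
                 if edges.shape[1] == connectome.n_edges(100) else None)
        for kcomp in range(min(2, model.scca.n_components)):
            prof = posthoc.edge_loadings(edges, fc_scores[:, kcomp],
                                         edge_names=names)
            tab = prof.table.copy()
            tab["q"] = latent.bh_fdr(np.nan_to_num(tab["p"].to_numpy(), nan=1.0))
            tab.to_csv(out / "tables" / f"edge_loadings_c{kcomp + 1}.csv",
                       index=False)
            nprof = posthoc.nps_loadings(nps, nps_scores[:, kcomp])
            nprof.table.to_csv(out / "tables" / f"nps_loadings_c{kcomp + 1}.csv",
                               index=False)
            if atlas is not None:
                contrib = posthoc.network_contribution(
                    np.nan_to_num(prof.table["r"].to_numpy()), atlas
                )
                contrib.table.to_csv(
                    out / "tables" / f"network_contribution_c{kcomp + 1}.csv"
                )
        lmm_summary = None
        if longitudinal is not None and "subtype" in getattr(
            longitudinal, "columns", []
        ):
            lmm = posthoc.fit_lmm(longitudinal, phenotype="value",
                                  reference_subtype=config.k)
            lmm_summary = {
                "interaction_F": lmm.interaction_F,
                "interaction_p": lmm.interaction_p,
                "params": {k: float(v) for k, v in lmm.params.items()},
            }
        report["stages"]["posthoc"] = {"lmm": lmm_summary}

        if cohort is not None:
            from sklearn.metrics import adjusted_rand_score

            report["stages"]["truth_recovery"] = {
                "ari_vs_true_labels": float(
                    adjusted_rand_score(
                        cohort.true_labels[cluster_rows], subtypes.labels
                    )
                ),
                "fc_score_truth_corr": [
                    float(abs(np.corrcoef(fc_scores[:, k],
                                          cohort.true_latent[:, k])[0, 1]))
                    for k in range(min(model.scca.n_components,
                                       cohort.true_latent.shape[1]))
                ],
            }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _atomic_write(out / "report.json",
                      json.dumps(report, indent=1, sort_keys=True,
                                 default=_json_default))
        _atomic_write(out / "log.txt", "\n".join(log_lines) + "\n")
        raise

    _atomic_write(out / "report.json",
                  json.dumps(report, indent=1, sort_keys=True,
                             default=_json_default))
    _atomic_write(out / "log.txt", "\n".join(log_lines) + "\n")
    log("done")
    return report


def run_replication(
    config: RunConfig,
    discovery_dir: str | Path,
    out_dir: str | Path,
) -> dict:
    """Frozen-model transfer onto a replication cohort.

    Loads the discovery latent model and subtype centroids, transforms
    the replication data without any refitting, clusters from the
    discovery centroids, and reruns the descriptive post hoc summaries.
    """
    config.validate()
    disc = Path(discovery_dir)
    model_path = disc / "models" / "latent_model.json"
    subtypes_path = disc / "models" / "subtypes.json"
    for p in (model_path, subtypes_path):
        if not p.exists():
            raise FileNotFoundError(f"missing discovery artifact {p}")
    model = LatentModel.from_json(model_path.read_text())
    sub_doc = json.loads(subtypes_path.read_text())
    centroids = np.asarray(sub_doc["centroids"], dtype=float)

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)

    edges, nps, phenotype, longitudinal, cohort = _load_inputs(
        config, stage_seeds(config.seed)["cohort"]
    )
    if edges.shape[1] != model.scca.x_mean.size:
        raise ValueError(
            f"replication edge count {edges.shape[1]} does not match the "
            f"frozen model ({model.scca.x_mean.size})"
        )
    fc_scores, nps_scores = model.transform(edges, nps)
    latent_r = [
        float(np.corrcoef(fc_scores[:, k], nps_scores[:, k])[0, 1])
        for k in range(model.scca.n_components)
    ]
    scores = fc_scores[:, :2]
    if sub_doc.get("standardize_latent"):
        scores = (scores - scores.mean(0)) / scores.std(0, ddof=1)
    transfer = subtyping.transfer_subtypes(scores, centroids)
    labels_df = pd.DataFrame(
        {
            "row": np.arange(scores.shape[0]),
            "subtype": transfer.labels + 1,
            "initial_subtype": transfer.initial_labels + 1,
        }
    )
    labels_df.to_csv(out / "tables" / "replication_labels.csv", index=False)
    report = {
        "package": "fcsubtypes",
        "kind": "replication",
        "latent_r": latent_r,
        "sizes": np.bincount(transfer.labels,
                             minlength=centroids.shape[0]).tolist(),
        "empty_clusters": transfer.empty_clusters,
        "initial_vs_final_agreement": float(
            (transfer.labels == transfer.initial_labels).mean()
        ),
    }
    if cohort is not None:
        from sklearn.metrics import adjusted_rand_score

        report["ari_vs_true_labels"] = float(
            adjusted_rand_score(cohort.true_labels, transfer.labels)
        )
    _atomic_write(out / "report.json",
                  json.dumps(report, indent=1, sort_keys=True,
                             default=_json_default))
    return report
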