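"""Synthetic cohorts with planted FC--symptom structure.

The generator emulates the statistical skeleton that the analysis
pipeline assumes in a dementia-like cohort:

* a small number of latent *subsyndrome severities* ``z`` per participant,
  drawn from a Gaussian mixture whose components are the planted
  neurophysiological subtypes;
* a sparse, calibrated cross-covariance between ``z`` and the two observed
  views — connectome edge vectors and 12 ordinal neuropsychiatric symptom
  (NPS) domain scores (0-3, Neuropsychiatric Inventory style);
* subtype-specific longitudinal decline of a clinical measure, with
  participant-level random intercepts.

Calibration convention: ``canonical_strength[k]`` is the population
Pearson correlation between ``z_k`` and the projection of the edge view
onto the true (unit-norm) edge weight vector, i.e. the strength of the
FC side of the planted canonical pair.  The symptom side is generated
with high fidelity (``nps_strength``, default 0.95) so that the
cross-view canonical correlation is approximately ``canonical_strength``
itself: symptoms *define* the latent severity, connectivity reflects it
noisily.  Residual variance on signal-carrying edges is mostly shared
within a latent dimension (``shared_noise_frac``), mimicking the
spatially structured residual fluctuations of real FC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import n_edges

__all__ = [
    "NPS_DOMAINS",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null",
    "generate_longitudinal",
    "generate_timeseries",
    "latent_mixture_variance",
]

#: Neuropsychiatric Inventory domain names (12 domains, ordinal 0-3).
NPS_DOMAINS = (
    "delusions",
    "hallucinations",
    "agitation",
    "depression",
    "anxiety",
    "euphoria",
    "apathy",
    "disinhibition",
    "irritability",
    "aberrant_motor",
    "nighttime_behavior",
    "appetite",
)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic cohort is drawn.

    Defaults describe the study-sized benchmark: ~180 participants, a
    100-ROI connectome (4950 edges), 12 ordinal NPS domains, two planted
    canonical dimensions of strength (0.6, 0.4), and three subtypes in
    the latent plane whose mixing proportions follow the 45/43/66 split
    of a moderately sized memory-clinic cohort (two symptomatic subtypes
    displaced along one latent axis each, one mild subtype at the
    origin, adjacent centroids 4 within-cluster SDs apart).
    """

    n_participants: int = 180
    n_rois: int = 100
    n_nps_domains: int = 12
    n_latent: int = 2
    edge_support_size: int = 10
    nps_support_size: int = 4
    canonical_strength: tuple[float, ...] = (0.6, 0.4)
    nps_strength: float = 0.95
    cluster_centroids: tuple[tuple[float, ...], ...] = (
        (4.0, 0.0),
        (0.0, 4.0),
        (0.0, 0.0),
    )
    cluster_proportions: tuple[float, ...] = (0.29, 0.28, 0.43)
    cluster_sd: float = 1.0
    noise_sd: float = 1.0
    shared_noise_frac: float = 0.9
    ordinal_thresholds: tuple[float, float, float] = (0.8, 1.8, 2.8)
    n_visits: int = 4
    visit_spacing: float = 1.0
    subtype_slopes: tuple[float, ...] = (0.05, 0.05, 0.0)
    longitudinal_noise_sd: float = 0.12
    longitudinal_intercept_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("need at least 2 participants")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-12:
            raise ConfigurationError("cluster_proportions must sum to 1 within 1e-12")
        if any(p < 0 for p in self.cluster_proportions):
            raise ConfigurationError("cluster_proportions must be non-negative")
        if len(self.cluster_centroids) != len(self.cluster_proportions):
            raise ConfigurationError("one proportion per centroid required")
        if any(len(c) != self.n_latent for c in self.cluster_centroids):
            raise ConfigurationError("centroids must live in the latent plane")
        if len(self.canonical_strength) != self.n_latent:
            raise ConfigurationError("one canonical_strength per latent dimension")
        if any(not (0.0 <= r < 1.0) for r in self.canonical_strength):
            raise ConfigurationError("canonical_strength values must lie in [0, 1)")
        if not (0.0 < self.nps_strength <= 1.0):
            raise ConfigurationError("nps_strength must lie in (0, 1]")
        if self.n_latent * self.edge_support_size > n_edges(self.n_rois):
            raise ConfigurationError(
                "disjoint edge supports exceed the number of edges"
            )
        if self.n_latent * self.nps_support_size > self.n_nps_domains:
            raise ConfigurationError(
                "disjoint NPS supports exceed the number of domains"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not (0.0 <= self.shared_noise_frac <= 1.0):
            raise ConfigurationError("shared_noise_frac must lie in [0, 1]")
        t = self.ordinal_thresholds
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ConfigurationError("ordinal_thresholds must be 3 increasing cuts")
        if len(self.subtype_slopes) != len(self.cluster_proportions):
            raise ConfigurationError("one longitudinal slope per subtype")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_rois)


@dataclass
class SyntheticCohort:
    """One generated cohort plus the ground truth used to plant it."""

    edges: np.ndarray                 # n x E
    nps: np.ndarray                   # n x 12, integer 0-3
    true_latent: np.ndarray           # n x n_latent
    true_labels: np.ndarray           # n, 0-based cluster ids
    true_edge_weights: np.ndarray     # n_latent x E, unit-norm sparse rows
    true_nps_weights: np.ndarray      # n_latent x 12, unit-norm sparse rows
    phenotype: pd.DataFrame           # stylized clinical covariates
    longitudinal: pd.DataFrame        # participant, visit time, measure value
    participant_ids: list[str]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        n = self.edges.shape[0]
        if not (
            self.nps.shape[0] == self.true_latent.shape[0]
            == self.true_labels.shape[0] == len(self.participant_ids) == n
        ):
            raise ValueError("inconsistent participant counts across components")
        if not np.isfinite(self.edges).all():
            raise ValueError("edges contain non-finite values")
        if not np.isin(self.nps, [0, 1, 2, 3]).all():
            raise ValueError("NPS scores must be ordinal 0-3")


def latent_mixture_variance(config: GeneratorConfig) -> np.ndarray:
    """Population variance of each latent dimension under the mixture."""
    mu = np.asarray(config.cluster_centroids, dtype=float)
    w = np.asarray(config.cluster_proportions, dtype=float)
    mean = w @ mu
    between = w @ (mu - mean) ** 2
    return config.cluster_sd**2 + between


def _disjoint_supports(
    rng: np.random.Generator, dim: int, size: int, k: int
) -> list[np.ndarray]:
    chosen = rng.choice(dim, size=size * k, replace=False)
    return [np.sort(chosen[i * size : (i + 1) * size]) for i in range(k)]


def _sparse_unit_rows(supports: list[np.ndarray], dim: int) -> np.ndarray:
    w = np.zeros((len(supports), dim))
    for k, s in enumerate(supports):
        w[k, s] = 1.0 / np.sqrt(len(s))
    return w


def generate_cohort(
    config: GeneratorConfig, replicate_seed: int | None = None
) -> SyntheticCohort:
    """Draw one cohort; bit-reproducible from ``config`` (incl. its seed).

    ``replicate_seed`` draws a fresh, independent cohort from the *same*
    generative model: the planted structure (supports, weights, noise
    calibration) is still controlled by ``config.seed``, only the
    participant-level randomness changes.  This is how discovery and
    replication cohorts of one study are simulated.
    """
    rng_structure = np.random.default_rng(config.seed)
    rng = np.random.default_rng(
        config.seed if replicate_seed is None else replicate_seed
    )
    n, e, q = config.n_participants, config.n_edges, config.n_nps_domains
    kdim = config.n_latent

    edge_support = _disjoint_supports(rng_structure, e, config.edge_support_size, kdim)
    nps_support = _disjoint_supports(rng_structure, q, config.nps_support_size, kdim)

    labels = rng.choice(config.n_clusters, size=n, p=config.cluster_proportions)
    centroids = np.asarray(config.cluster_centroids, dtype=float)
    z = centroids[labels] + config.cluster_sd * rng.standard_normal((n, kdim))

    sigma_z = np.sqrt(latent_mixture_variance(config))

    u_true = _sparse_unit_rows(edge_support, e)
    v_true = _sparse_unit_rows(nps_support, q)

    # --- edge view -------------------------------------------------------
    sigma = config.noise_sd
    phi = config.shared_noise_frac
    s = config.edge_support_size
    edges = sigma * rng.standard_normal((n, e))
    for k in range(kdim):
        rho = config.canonical_strength[k]
        shared = rng.standard_normal(n)  # dimension-wide residual factor
        sup = edge_support[k]
        noise = sigma * (
            np.sqrt(phi) * shared[:, None]
            + np.sqrt(1.0 - phi) * rng.standard_normal((n, len(sup)))
        )
        if rho > 0 and sigma > 0:
            # a solves corr(z_k, X u_k) = rho for uniform unit-norm u_k
            a = (
                rho * sigma * np.sqrt(phi + (1.0 - phi) / s)
                / (sigma_z[k] * np.sqrt(s) * np.sqrt(1.0 - rho**2))
            ) * np.sqrt(s)  # per-edge amplitude
            edges[:, sup] = a * z[:, [k]] + noise
        elif sigma == 0:
            edges[:, sup] = z[:, [k]] * (1.0 / np.sqrt(s))
        else:
            edges[:, sup] = noise

    # --- symptom view ----------------------------------------------------
    zeta = config.nps_strength
    sq = config.nps_support_size
    y = rng.standard_normal((n, q))
    for k in range(kdim):
        sup = nps_support[k]
        if zeta >= 1.0:
            y[:, sup] = z[:, [k]]
        else:
            b = zeta / (sigma_z[k] * np.sqrt(sq) * np.sqrt(1.0 - zeta**2))
            y[:, sup] = b * z[:, [k]] + rng.standard_normal((n, len(sup)))
    nps = np.digitize(y, config.ordinal_thresholds)

    # --- stylized clinical covariates ------------------------------------
    ids = [f"S{i:04d}" for i in range(n)]
    sev = z.sum(axis=1)
    norms = np.linalg.norm(centroids, axis=1)
    top = norms.max() if norms.max() > 0 else 1.0
    p_dem = 0.35 + 0.3 * norms / top
    phenotype = pd.DataFrame(
        {
            "participant_id": ids,
            "subtype": labels + 1,  # 1-based, as reported clinically
            "diagnosis": (rng.random(n) < p_dem[labels]).astype(int),
            "age": np.round(rng.normal(74, 6, size=n), 1),
            "sex": rng.integers(0, 2, size=n),
            "mmse": np.clip(np.round(29 - 0.8 * sev + rng.normal(0, 1.5, n)), 0, 30),
            "cdr_sb": np.clip(np.round(0.5 * sev + rng.normal(0, 0.8, n), 1), 0, 18),
            "faq": np.clip(np.round(1.5 * sev + rng.normal(0, 2.0, n)), 0, 30),
        }
    )

    longitudinal = generate_longitudinal(config, labels, rng=rng, ids=ids)

    return SyntheticCohort(
        edges=edges,
        nps=nps,
        true_latent=z,
        true_labels=labels,
        true_edge_weights=u_true,
        true_nps_weights=v_true,
        phenotype=phenotype,
        longitudinal=longitudinal,
        participant_ids=ids,
        config=config,
    )


def generate_longitudinal(
    config: GeneratorConfig,
    labels: np.ndarray,
    rng: np.random.Generator | int | None = None,
    ids: Sequence[str] | None = None,
    measure: str = "orientation",
) -> pd.DataFrame:
    """Longitudinal records with subtype-specific linear slopes.

    value(i, t) = intercept_i + slope(subtype_i) * t + noise, with
    Gaussian random intercepts and visits on the configured grid.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != config.n_participants:
        raise ValueError("labels length must equal n_participants")
    if labels.min() < 0 or labels.max() >= config.n_clusters:
        raise ValueError(f"unknown subtype label id {labels.max()}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    n = config.n_participants
    if ids is None:
        ids = [f"S{i:04d}" for i in range(n)]
    slopes = np.asarray(config.subtype_slopes, dtype=float)[labels]
    intercepts = rng.normal(0.0, config.longitudinal_intercept_sd, size=n)
    times = np.arange(config.n_visits) * config.visit_spacing
    rows = []
    for visit, t in enumerate(times):
        noise = rng.normal(0.0, config.longitudinal_noise_sd, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "subtype": labels + 1,
                    "visit": visit,
                    "time": t,
                    "measure": measure,
                    "value": intercepts + slopes * t + noise,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).sort_values(
        ["participant_id", "visit"], ignore_index=True
    )


def generate_null(n: int, p: int, q: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two mutually independent standard-Gaussian views (calibration input)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if p < 1 or q < 1:
        raise ValueError("views must have at least one column")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, p)), rng.standard_normal((n, q))


def generate_timeseries(
    correlation: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """ROI x time Gaussian series with the given population correlation.

    Exercises the connectome path end to end: the sample FC of the output
    converges to ``correlation`` at rate O(1/sqrt(T)).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    c = np.asarray(correlation, dtype=float)
    # eigenvalue clip keeps nearly-PSD inputs usable
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    return root @ rng.standard_normal((c.shape[0], n_timepoints))
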