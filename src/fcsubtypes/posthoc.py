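"""Post hoc characterization of subsyndromes and subtypes.

Given fitted latent scores and subtype labels, this module computes the
descriptive and inferential statistics used to interpret them: per-edge
Pearson loadings and per-domain Spearman loadings of the latent scores,
7x7 network-contribution summaries of any per-edge quantity, two-group
per-edge rank-sum tests with BH-FDR (patients in one subtype vs
controls), omnibus phenotype comparisons across subtypes (chi-square /
Kruskal-Wallis with Dunn pairwise follow-up), and longitudinal linear
mixed-effects progression models with a random intercept per
participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .connectome import SEVEN_NETWORKS, NetworkAtlas, n_edges
from .latent import bh_fdr

__all__ = [
    "LoadingProfile",
    "NetworkContribution",
    "GroupComparison",
    "PhenotypeComparison",
    "LMMResult",
    "edge_loadings",
    "nps_loadings",
    "network_contribution",
    "group_edge_test",
    "phenotype_compare",
    "fit_lmm",
    "latent_phenotype_assoc",
]


# --------------------------------------------------------------------------
# Loadings


@dataclass
class LoadingProfile:
    """Correlation loadings of one latent score against raw features."""

    table: pd.DataFrame                # feature, r (or rho), p
    kind: str                          # "pearson" | "spearman"
    n_undefined: int = 0               # constant features, reported missing


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r and two-sided p (t-distribution)."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ yc / np.where(denom == 0, 1, denom), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def edge_loadings(edges: np.ndarray, latent: np.ndarray,
                  edge_names: list[str] | None = None) -> LoadingProfile:
    """Pearson correlation of every edge with an FC-side latent score."""
    edges = np.asarray(edges, dtype=float)
    latent = np.asarray(latent, dtype=float).ravel()
    if edges.shape[0] != latent.shape[0]:
        raise ValueError("edges and latent scores must have aligned rows")
    r, p = _pearson_columns(edges, latent)
    names = edge_names if edge_names is not None else [
        f"edge{i}" for i in range(edges.shape[1])
    ]
    table = pd.DataFrame({"feature": names, "r": r, "p": p})
    return LoadingProfile(table=table, kind="pearson",
                          n_undefined=int(np.isnan(r).sum()))


def nps_loadings(nps: np.ndarray, latent: np.ndarray,
                 domain_names: list[str] | None = None) -> LoadingProfile:
    """Spearman correlation (midrank ties) of each ordinal NPS domain
    with an NPS-side latent score."""
    nps = np.asarray(nps, dtype=float)
    latent = np.asarray(latent, dtype=float).ravel()
    if nps.shape[0] != latent.shape[0]:
        raise ValueError("nps and latent scores must have aligned rows")
    rhos, ps = [], []
    for j in range(nps.shape[1]):
        col = nps[:, j]
        if np.all(col == col[0]):
            rhos.append(np.nan)
            ps.append(np.nan)
        else:
            rho, p = stats.spearmanr(col, latent)
            rhos.append(rho)
            ps.append(p)
    names = domain_names if domain_names is not None else [
        f"domain{j}" for j in range(nps.shape[1])
    ]
    table = pd.DataFrame({"feature": names, "rho": rhos, "p": ps})
    return LoadingProfile(table=table, kind="spearman",
                          n_undefined=int(np.isnan(np.asarray(rhos)).sum()))


# --------------------------------------------------------------------------
# Network contribution summaries


@dataclass
class NetworkContribution:
    """7x7 symmetric table of summed |value| by network pair.

    The diagonal holds within-network sums; the table total equals the
    sum of |value| over all (unmasked) edges exactly.
    """

    table: pd.DataFrame
    statistic: str

    @property
    def total(self) -> float:
        """Sum over unordered network pairs; equals sum of |value| over edges."""
        return float(np.triu(self.table.values).sum())


def network_contribution(
    values: np.ndarray,
    atlas: NetworkAtlas,
    mask: np.ndarray | None = None,
    statistic: str = "|r|",
) -> NetworkContribution:
    """Aggregate a per-edge quantity into the 7x7 network grid.

    Entry (A, B) sums |value| over edges with one endpoint in network A
    and the other in B (within-network on the diagonal).  ``mask``
    optionally restricts the sum to, e.g., FDR-surviving edges.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size != n_edges(atlas.n_rois):
        raise ValueError("values are not aligned to the atlas edge layout")
    if mask is None:
        mask = np.ones(values.size, dtype=bool)
    lo, hi = atlas.edge_networks()
    nets = list(SEVEN_NETWORKS)
    tab = pd.DataFrame(0.0, index=nets, columns=nets)
    absv = np.abs(values) * mask
    for a in nets:
        for b in nets:
            if nets.index(b) < nets.index(a):
                continue
            sel = (lo == min(a, b)) & (hi == max(a, b))
            s = float(absv[sel].sum())
            tab.loc[a, b] = s
            tab.loc[b, a] = s
    return NetworkContribution(table=tab, statistic=statistic)


# --------------------------------------------------------------------------
# Two-group per-edge rank tests


@dataclass
class GroupComparison:
    """Per-edge two-sample rank-sum results with BH-FDR."""

    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    network_summed_z: NetworkContribution | None = None


def rank_sum_z(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilcoxon rank-sum (Mann-Whitney) normal approximation
    with midranks and tie correction, per column; no continuity
    correction.  Returns (z, two-sided p)."""
    g1 = np.atleast_2d(np.asarray(g1, dtype=float))
    g2 = np.atleast_2d(np.asarray(g2, dtype=float))
    n1, n2 = g1.shape[0], g2.shape[0]
    ntot = n1 + n2
    pooled = np.vstack([g1, g2])
    ranks = stats.rankdata(pooled, axis=0)
    w = ranks[:n1].sum(axis=0)
    mu = n1 * (ntot + 1) / 2.0
    # tie correction per column; only columns that actually contain ties
    srt = np.sort(pooled, axis=0)
    tie_term = np.zeros(srt.shape[1])
    has_ties = (srt[1:] == srt[:-1]).any(axis=0)
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(srt[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((ntot + 1) - tie_term / (ntot * (ntot - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(var > 0, p, 1.0)
    return z, p


def group_edge_test(
    edges_group1: np.ndarray,
    edges_group2: np.ndarray,
    atlas: NetworkAtlas | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Per-edge Wilcoxon rank-sum comparison of two independent groups.

    BH-FDR across edges; when an atlas is supplied, |z| of the
    FDR-surviving edges is additionally summed by network pair (the
    "summed absolute z" characterization of abnormal connectivity).
    """
    g1 = np.asarray(edges_group1, dtype=float)
    g2 = np.asarray(edges_group2, dtype=float)
    if g1.ndim != 2 or g2.ndim != 2 or g1.shape[1] != g2.shape[1]:
        raise ValueError("groups must be 2-D with the same edge count")
    if g1.shape[0] < 3 or g2.shape[0] < 3:
        raise ValueError("each group needs at least 3 participants")
    z, p = rank_sum_z(g1, g2)
    q = bh_fdr(p)
    sig = q < alpha
    net = None
    if atlas is not None:
        net = network_contribution(z, atlas, mask=sig, statistic="|z|")
    return GroupComparison(z=z, p=p, q=q, significant=sig,
                           network_summed_z=net)


# --------------------------------------------------------------------------
# Phenotype comparisons across >= 3 subtypes


@dataclass
class PhenotypeComparison:
    kind: str                          # "categorical" | "ordinal"
    statistic: float                   # chi2 or Kruskal-Wallis H
    p: float
    group_summary: pd.DataFrame
    pairwise: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray,
                   levels: np.ndarray) -> pd.DataFrame:
    """Dunn z tests on pooled midranks with tie correction, BH-adjusted."""
    ranks = stats.rankdata(values)
    ntot = values.size
    _, counts = np.unique(values, return_counts=True)
    tie = (counts**3 - counts).sum()
    var_unit = ntot * (ntot + 1) / 12.0 - tie / (12.0 * (ntot - 1))
    rows = []
    for a, b in combinations(levels, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        se = np.sqrt(var_unit * (1.0 / ra.size + 1.0 / rb.size))
        zab = (ra.mean() - rb.mean()) / se
        rows.append({"group_a": a, "group_b": b, "z": zab,
                     "p": 2 * stats.norm.sf(abs(zab))})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def phenotype_compare(
    values: np.ndarray,
    groups: np.ndarray,
    kind: str = "ordinal",
) -> PhenotypeComparison:
    """Compare a phenotype across >= 2 subtype groups.

    ``categorical``: two-tailed chi-square on the contingency table
    (with a warning if any expected cell count falls below 1).
    ``ordinal`` (or continuous): Kruskal-Wallis omnibus followed by
    pairwise Dunn z tests with BH correction; medians and IQRs are
    reported per group.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must align")
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups")
    warns: list[str] = []
    if kind == "categorical":
        tab = pd.crosstab(pd.Series(groups, name="group"),
                          pd.Series(values, name="value"))
        chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy())
        if (expected < 1).any():
            warns.append("expected cell count below 1; chi-square unreliable")
        summary = tab.reset_index()
        return PhenotypeComparison(kind=kind, statistic=float(chi2),
                                   p=float(p), group_summary=summary,
                                   warnings=warns)
    vals = values.astype(float)
    samples = [vals[groups == g] for g in levels]
    stat, p = stats.kruskal(*samples)
    summary = pd.DataFrame(
        {
            "group": levels,
            "n": [s.size for s in samples],
            "median": [np.median(s) for s in samples],
            "q1": [np.percentile(s, 25) for s in samples],
            "q3": [np.percentile(s, 75) for s in samples],
        }
    )
    pairwise = _dunn_pairwise(vals, groups, levels)
    return PhenotypeComparison(kind="ordinal", statistic=float(stat),
                               p=float(p), group_summary=summary,
                               pairwise=pairwise, warnings=warns)


# --------------------------------------------------------------------------
# Longitudinal linear mixed-effects progression


@dataclass
class LMMResult:
    """Fixed effects of phenotype ~ subtype + time + subtype:time with a
    random intercept per participant (ML fit)."""

    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    interaction_F: float
    interaction_p: float
    random_intercept_var: float
    converged: bool
    singular: bool
    reference_subtype: int


def fit_lmm(
    long_records: pd.DataFrame,
    phenotype: str = "value",
    reference_subtype: int = 3,
) -> LMMResult:
    """Longitudinal progression model with subtype-specific slopes.

    ``long_records`` needs columns participant_id, subtype, time and the
    phenotype column.  The subtype main effects and time-by-subtype
    interactions are coded against ``reference_subtype`` (absorbed), and
    the interaction F statistic is the joint Wald test of all
    time-by-subtype terms.
    """
    df = long_records.copy()
    required = {"participant_id", "subtype", "time", phenotype}
    if not required <= set(df.columns):
        raise ValueError(f"longitudinal records need columns {sorted(required)}")
    if reference_subtype not in set(df["subtype"]):
        raise ValueError(f"reference subtype {reference_subtype} absent from data")
    visits = df.groupby("participant_id")["time"].nunique()
    if (visits >= 2).sum() < 2:
        raise ValueError("need at least two participants with >= 2 visits")
    df["subtype"] = df["subtype"].astype(int)
    formula = (
        f"{phenotype} ~ C(subtype, Treatment(reference={reference_subtype}))"
        f" * time"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        fit = model.fit(reml=False)
    names = [n for n in fit.params.index if ":time" in n and "Treatment" in n]
    if names:
        contrast = np.zeros((len(names), len(fit.params)))
        for i, nm in enumerate(names):
            contrast[i, list(fit.params.index).index(nm)] = 1.0
        ftest = fit.f_test(contrast)
        interaction_F = float(ftest.fvalue)
        interaction_p = float(ftest.pvalue)
    else:  # single subtype present
        interaction_F, interaction_p = 0.0, 1.0
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    return LMMResult(
        params=fit.params.drop("Group Var", errors="ignore"),
        tvalues=fit.tvalues.drop("Group Var", errors="ignore"),
        pvalues=fit.pvalues.drop("Group Var", errors="ignore"),
        interaction_F=interaction_F,
        interaction_p=interaction_p,
        random_intercept_var=re_var,
        converged=bool(fit.converged),
        singular=re_var < 1e-10,
        reference_subtype=reference_subtype,
    )


# --------------------------------------------------------------------------
# Latent-score / phenotype associations


def latent_phenotype_assoc(
    latent: np.ndarray,
    phenotype: pd.DataFrame,
    continuous: list[str] = (),
    categorical: list[str] = (),
) -> pd.DataFrame:
    """Pearson r (continuous measures) and one-way ANOVA F (categorical
    measures, e.g. sex) against each latent component."""
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    if latent.shape[0] == 1:
        latent = latent.T
    rows = []
    for k in range(latent.shape[1]):
        score = latent[:, k]
        for col in continuous:
            x = pd.to_numeric(phenotype[col], errors="coerce").to_numpy()
            ok = np.isfinite(x) & np.isfinite(score)
            if ok.sum() < 3:
                rows.append({"component": k + 1, "measure": col,
                             "test": "pearson", "statistic": np.nan,
                             "p": np.nan, "n": int(ok.sum())})
                continue
            r, p = stats.pearsonr(score[ok], x[ok])
            rows.append({"component": k + 1, "measure": col,
                         "test": "pearson", "statistic": r, "p": p,
                         "n": int(ok.sum())})
        for col in categorical:
            g = phenotype[col].to_numpy()
            ok = np.isfinite(score) & pd.notna(g)
            levels = np.unique(g[ok])
            samples = [score[ok & (g == lv)] for lv in levels]
            samples = [s for s in samples if s.size > 0]
            if len(samples) < 2:
                rows.append({"component": k + 1, "measure": col,
                             "test": "anova", "statistic": np.nan,
                             "p": np.nan, "n": int(ok.sum())})
                continue
            f, p = stats.f_oneway(*samples)
            rows.append({"component": k + 1, "measure": col,
                         "test": "anova", "statistic": f, "p": p,
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)
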