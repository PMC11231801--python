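"""Functional connectivity construction and the canonical edge-vector layout.

A participant's resting-state activity is summarized as a parcellated
ROI x time matrix (Schaefer-style 100-region cortical atlas by default).
Functional connectivity (FC) is the Pearson correlation between every
pair of ROI time series; the strictly-upper triangle of that matrix,
read in row-major order, is the *edge vector* that every downstream
stage (sparse CCA, loadings, group tests) consumes.  `vectorize` and
`devectorize` are exact inverses, so the edge ordering convention lives
in exactly one place.

ROI indices are 0-based internally; file headers use 1-based atlas
labels (``roi1_roi2`` is the edge between the first and second ROI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcellatedTimeSeries",
    "ConnectivityMatrix",
    "EdgeVector",
    "NetworkAtlas",
    "SEVEN_NETWORKS",
    "compute_fc",
    "vectorize",
    "devectorize",
    "fisher_z",
    "edge_pairs",
    "edge_columns",
    "n_edges",
    "read_edge_table",
    "read_timeseries",
    "load_atlas",
    "default_atlas",
]

#: The seven canonical resting-state networks.
SEVEN_NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPC", "DMN")

_ASYMMETRY_TOL = 1e-10


class DegenerateInputError(ValueError):
    """Raised for inputs the correlation pipeline cannot process (zero
    variance ROIs, too few timepoints, asymmetric matrices)."""


def n_edges(n_rois: int) -> int:
    """Number of unique edges among ``n_rois`` regions: R(R-1)/2."""
    return n_rois * (n_rois - 1) // 2


def edge_pairs(n_rois: int) -> np.ndarray:
    """(E, 2) array of 0-based (i, j) ROI pairs, i < j, row-major order."""
    iu = np.triu_indices(n_rois, k=1)
    return np.column_stack(iu)


def edge_columns(n_rois: int) -> list[str]:
    """Canonical edge column names, 1-based: ``roi{i}_roi{j}`` with i < j."""
    return [f"roi{i + 1}_roi{j + 1}" for i, j in edge_pairs(n_rois)]


@dataclass
class ParcellatedTimeSeries:
    """ROI x timepoint signal matrix for one participant."""

    values: np.ndarray
    roi_labels: Sequence[str] | None = None
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D ROI x time matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing/non-finite values")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{i + 1}" for i in range(self.values.shape[0])]
        if len(self.roi_labels) != self.values.shape[0]:
            raise ValueError("roi_labels length does not match number of rows")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(v - v.T).max() > _ASYMMETRY_TOL:
            raise DegenerateInputError(
                f"matrix asymmetric beyond tolerance {_ASYMMETRY_TOL}"
            )
        if self.roi_labels is None:
            self.roi_labels = [f"roi{i + 1}" for i in range(v.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Upper-triangle vectorization of a connectivity matrix.

    ``values[e]`` is the correlation of the ROI pair ``edge_index[e]``;
    pairs are (i, j) with i < j in row-major (lexicographic) order.
    """

    values: np.ndarray
    n_rois: int
    edge_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = n_edges(self.n_rois)
        if self.values.size != expected:
            raise ValueError(
                f"edge vector for {self.n_rois} ROIs must have length "
                f"{expected}, got {self.values.size}"
            )
        if self.edge_index is None:
            self.edge_index = edge_pairs(self.n_rois)


def compute_fc(ts: ParcellatedTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity of a time-series matrix.

    Entry (i, j) is the Pearson correlation of ROI series i and j; the
    diagonal is exactly 1.  Invariant to positive affine rescaling of
    any single ROI series.
    """
    if ts.n_timepoints < 3:
        raise DegenerateInputError(
            f"need at least 3 timepoints, got {ts.n_timepoints}"
        )
    sd = ts.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(str(ts.roi_labels[i]) for i in dead[:5])
        raise DegenerateInputError(f"zero-variance ROI series: {names}")
    cm = np.corrcoef(ts.values)
    np.fill_diagonal(cm, 1.0)
    # exact symmetry guard against floating-point asymmetry
    cm = (cm + cm.T) / 2.0
    return ConnectivityMatrix(values=cm, roi_labels=list(ts.roi_labels))


def vectorize(cm: ConnectivityMatrix) -> EdgeVector:
    """Extract the strictly-upper triangle in row-major order."""
    r = cm.n_rois
    iu = np.triu_indices(r, k=1)
    return EdgeVector(values=cm.values[iu], n_rois=r)


def devectorize(ev: EdgeVector, roi_labels: Sequence[str] | None = None) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix (unit diagonal) from an edge vector."""
    r = ev.n_rois
    m = np.eye(r)
    iu = np.triu_indices(r, k=1)
    m[iu] = ev.values
    m[(iu[1], iu[0])] = ev.values
    return ConnectivityMatrix(values=m, roi_labels=roi_labels)


def fisher_z(ev: EdgeVector) -> EdgeVector:
    """Elementwise Fisher z (atanh) variance-stabilizing transform.

    Off by default in the pipeline, which works on raw Pearson edges;
    provided for practitioners who prefer z-scaled edges.
    """
    v = np.asarray(ev.values)
    if np.any(np.abs(v) >= 1.0):
        raise DegenerateInputError(
            "fisher_z undefined for |r| >= 1; found perfectly correlated edge"
        )
    return EdgeVector(values=np.arctanh(v), n_rois=ev.n_rois)


def _infer_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_edge_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a participants x edges table, enforcing the canonical edge order.

    The file must have a header of ``roi{i}_roi{j}`` columns (1-based,
    i < j) and may carry a leading ``participant_id`` column.  Columns in
    non-canonical order are reordered (with a warning); missing or extra
    edge columns are an error — never silently dropped.

    Returns (participant ids, n x E float matrix).
    """
    df = pd.read_csv(path, sep=_infer_sep(path))
    if "participant_id" in df.columns:
        ids = df.pop("participant_id").astype(str).tolist()
    else:
        ids = [str(i) for i in range(len(df))]
    cols = list(df.columns)
    # infer ROI count from the edge count
    e = len(cols)
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(r) != e:
        raise ValueError(f"{e} edge columns do not correspond to a full upper triangle")
    canon = edge_columns(r)
    if cols != canon:
        if set(cols) != set(canon):
            missing = sorted(set(canon) - set(cols))[:5]
            raise ValueError(f"edge columns do not match canonical layout; e.g. missing {missing}")
        warnings.warn("edge columns were not in canonical order; reordering", stacklevel=2)
        df = df[canon]
    mat = df.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("edge table contains non-numeric or missing cells")
    return ids, mat


def read_timeseries(path: str | Path, participant_id: str | None = None) -> ParcellatedTimeSeries:
    """Read a delimited timepoints x ROI text file into a ParcellatedTimeSeries.

    Rows are timepoints, columns are ROIs labelled ``roi{i}``; stored
    internally as ROI x time.
    """
    df = pd.read_csv(path, sep=_infer_sep(path))
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:  # pragma: no cover - message detail
        raise ValueError(f"non-numeric cell in time-series file {path}") from exc
    return ParcellatedTimeSeries(
        values=values.T, roi_labels=list(df.columns), participant_id=participant_id
    )


@dataclass
class NetworkAtlas:
    """Assignment of each ROI to one of the seven canonical networks."""

    networks: Sequence[str]
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.networks = list(self.networks)
        unknown = sorted(set(self.networks) - set(SEVEN_NETWORKS))
        if unknown:
            raise ValueError(f"unknown network names: {unknown}")
        if self.roi_labels is None:
            self.roi_labels = [f"roi{i + 1}" for i in range(len(self.networks))]

    @property
    def n_rois(self) -> int:
        return len(self.networks)

    def edge_networks(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (network_a, network_b) sorted name pairs, canonical order."""
        pairs = edge_pairs(self.n_rois)
        nets = np.asarray(self.networks)
        a, b = nets[pairs[:, 0]], nets[pairs[:, 1]]
        swap = a > b
        lo = np.where(swap, b, a)
        hi = np.where(swap, a, b)
        return lo, hi


def load_atlas(path: str | Path) -> NetworkAtlas:
    """Load a two-column (roi, network) CSV into a NetworkAtlas."""
    df = pd.read_csv(path)
    if not {"roi", "network"} <= set(df.columns):
        raise ValueError("atlas file needs 'roi' and 'network' columns")
    return NetworkAtlas(networks=df["network"].tolist(), roi_labels=df["roi"].tolist())


def default_atlas() -> NetworkAtlas:
    """The packaged 100-ROI / 7-network lookup (synthetic, Schaefer-like)."""
    ref = resources.files("fcsubtypes").joinpath("data/atlas100_7net_synthetic.csv")
    with resources.as_file(ref) as p:
        return load_atlas(p)
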