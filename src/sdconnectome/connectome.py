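"""Weighted functional brain networks from ROI time series.

Each subject's network is built by (1) Pearson-correlating every pair of
subregion time courses, (2) variance-stabilising with Fisher's r-to-z
(arctanh), (3) taking absolute values — the sign of a resting-state
correlation is hard to interpret — and (4) normalising so all edge weights
lie in [0, 1]. The weighted node degree k_i = sum_j W_ij summarises how
strongly a subregion is coupled to the rest of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "AdjacencyMatrix",
    "DegreeVector",
    "Z_CAP",
    "build_network",
    "build_networks",
    "node_degree",
]

# Perfect correlations have infinite Fisher z; |r| is clipped just below 1 so
# the corresponding edge keeps a finite (maximal) weight.
_R_CLIP = 1.0 - 1e-7
Z_CAP = float(np.arctanh(_R_CLIP))


@dataclass
class RoiTimeSeries:
    """One subject's T x N matrix of subregion signal time courses."""

    subject_id: str
    data: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        if self.data.shape[1] != len(self.node_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.node_labels)} labels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def constant_columns(self) -> list[str]:
        sd = self.data.std(axis=0)
        return [lab for lab, s in zip(self.node_labels, sd) if s == 0.0]


@dataclass
class AdjacencyMatrix:
    """Symmetric N x N weighted network with edge weights in [0, 1] and a
    zero diagonal (self-connections are excluded)."""

    subject_id: str
    W: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if len(self.node_labels) != n:
            raise ValueError("label count does not match matrix size")
        self.validate()

    def validate(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.W, self.W.T, atol=atol):
            raise ValueError(f"subject {self.subject_id}: adjacency not symmetric")
        if np.any(np.diag(self.W) != 0.0):
            raise ValueError(f"subject {self.subject_id}: nonzero diagonal")
        if self.W.min() < -atol or self.W.max() > 1.0 + atol:
            raise ValueError(f"subject {self.subject_id}: weights outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class DegreeVector:
    """Weighted node degree k_i = sum_{j != i} W_ij for one subject."""

    subject_id: str
    k: np.ndarray
    node_labels: list[str]


def _fisher_z_abs(ts: RoiTimeSeries) -> np.ndarray:
    """|arctanh(r)| with a zeroed diagonal; |r| clipped below 1 with a warning."""
    constant = ts.constant_columns()
    if constant:
        raise ValueError(
            f"subject {ts.subject_id}: constant time course for subregion(s) "
            f"{constant} — correlation undefined"
        )
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a meaningful correlation")
    r = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= _R_CLIP):
        warnings.warn(
            f"subject {ts.subject_id}: perfectly correlated subregion pair(s); "
            f"Fisher z clipped at {Z_CAP:.3f}",
            stacklevel=3,
        )
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    return np.abs(np.arctanh(r))


def build_network(ts: RoiTimeSeries, normalization: str = "subject") -> AdjacencyMatrix:
    """Build one subject's weighted network.

    Parameters
    ----------
    ts : RoiTimeSeries
    normalization : {"subject", "none"}
        ``"subject"`` divides by the subject's off-diagonal maximum |z| so the
        strongest edge has weight 1. ``"none"`` returns raw |z| values scaled
        by the global cap (still in [0, 1]); used internally by the
        cohort-wide mode of :func:`build_networks`.
    """
    z = _fisher_z_abs(ts)
    if normalization == "subject":
        zmax = z.max()
        if zmax > 0:
            z = z / zmax
    elif normalization == "none":
        z = z / Z_CAP
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    return AdjacencyMatrix(ts.subject_id, z, list(ts.node_labels))


def build_networks(
    ts_list: list[RoiTimeSeries], normalization: str = "subject"
) -> list[AdjacencyMatrix]:
    """Build every subject's network.

    ``normalization="subject"`` (default) rescales each subject by their own
    maximum edge; ``"cohort"`` divides all subjects by the cohort-wide maximum
    |z|, preserving between-subject weight comparability.
    """
    if normalization == "subject":
        return [build_network(ts, "subject") for ts in ts_list]
    if normalization == "cohort":
        zs = [_fisher_z_abs(ts) for ts in ts_list]
        zmax = max(z.max() for z in zs)
        if zmax == 0:
            zmax = 1.0
        return [
            AdjacencyMatrix(ts.subject_id, z / zmax, list(ts.node_labels))
            for ts, z in zip(ts_list, zs)
        ]
    raise ValueError(f"unknown normalization: {normalization!r}")


def node_degree(adj: AdjacencyMatrix) -> DegreeVector:
    """Weighted degree k_i = sum_j W_ij (diagonal is zero by construction)."""
    adj.validate()
    return DegreeVector(adj.subject_id, adj.W.sum(axis=1), list(adj.node_labels))
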