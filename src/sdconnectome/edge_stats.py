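"""Edge-wise group comparison and leakage-safe significance masks.

Candidate dysfunctional connections are screened by an edge-wise two-sample
t-test on edge weights between the patient (SD) and control (HC) groups.
Benjamini–Hochberg adjusted q-values are computed and reported for every
edge; by default the selection mask uses the *uncorrected* p < alpha
criterion (the group screen feeds a classifier, not an inference), with
``criterion="q"`` available to mask on the adjusted values instead.

To keep feature selection from leaking the test subject into training, a
*mask family* holds one mask per leave-one-out fold, each recomputed with
that fold's subject excluded, alongside the full-cohort mask used for group
description.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import AdjacencyMatrix

__all__ = [
    "GROUP_SD",
    "GROUP_HC",
    "EdgeStatTable",
    "MaskFamily",
    "edge_weight_matrix",
    "edgewise_ttest",
    "bh_fdr",
    "build_mask_family",
]

GROUP_SD = "SD"
GROUP_HC = "HC"


def _check_groups(groups: np.ndarray) -> None:
    bad = set(groups) - {GROUP_SD, GROUP_HC}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; allowed: SD, HC")


def edge_weight_matrix(adjs: list[AdjacencyMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack upper-triangle edge weights into a subjects x edges matrix.

    Returns ``(E, iu, ju)`` where ``E[s, e]`` is subject s's weight on edge
    ``(iu[e], ju[e])`` with ``iu < ju`` in lexicographic order.
    """
    if not adjs:
        raise ValueError("no subjects")
    labels = adjs[0].node_labels
    for a in adjs:
        if a.node_labels != labels:
            raise ValueError("subjects have inconsistent node ordering")
    n = adjs[0].n_nodes
    iu, ju = np.triu_indices(n, k=1)
    E = np.stack([a.W[iu, ju] for a in adjs])
    return E, iu, ju


def _group_ttest(E_sd: np.ndarray, E_hc: np.ndarray, welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample t over edge columns; degenerate edges get p=1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(E_sd, E_hc, axis=0, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero variance in both groups; "
            "p set to 1",
            stacklevel=3,
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    return t, p


@dataclass
class EdgeStatTable:
    """Per-edge t statistics, p-values and BH q-values for one subject set."""

    table: pd.DataFrame  # columns: i, j, node_i, node_j, t, p, q, mean_sd, mean_hc
    n_nodes: int

    def __len__(self) -> int:
        return len(self.table)

    def p_matrix(self) -> np.ndarray:
        """Symmetric N x N matrix of p-values (diagonal = 1)."""
        P = np.ones((self.n_nodes, self.n_nodes))
        i = self.table["i"].to_numpy()
        j = self.table["j"].to_numpy()
        P[i, j] = P[j, i] = self.table["p"].to_numpy()
        return P


def edgewise_ttest(
    adjs: list[AdjacencyMatrix],
    groups,
    welch: bool = False,
) -> EdgeStatTable:
    """Two-sample t-test on every edge weight between SD and HC subjects.

    Pooled-variance Student's t by default; ``welch=True`` drops the equal
    variance assumption. p-values are two-sided; q-values are BH step-up
    adjusted across all N(N-1)/2 edges.
    """
    groups = np.asarray(groups)
    _check_groups(groups)
    E, iu, ju = edge_weight_matrix(adjs)
    if len(groups) != E.shape[0]:
        raise ValueError("group labels do not match subject count")
    sd = groups == GROUP_SD
    hc = groups == GROUP_HC
    if sd.sum() < 2 or hc.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = _group_ttest(E[sd], E[hc], welch)
    labels = adjs[0].node_labels
    table = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "node_i": [labels[k] for k in iu],
            "node_j": [labels[k] for k in ju],
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "mean_sd": E[sd].mean(axis=0),
            "mean_hc": E[hc].mean(axis=0),
        }
    )
    return EdgeStatTable(table, n_nodes=adjs[0].n_nodes)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg linear step-up adjusted p-values.

    q_(k) = min_{j >= k} m * p_(j) / j, capped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MaskFamily:
    """Full-cohort significance mask plus one leave-one-out mask per subject.

    ``fold_masks[s]`` is computed with subject ``s`` excluded, so the feature
    set used to predict subject ``s`` never saw their data.
    """

    full_mask: np.ndarray
    fold_masks: list[np.ndarray]
    alpha: float
    criterion: str = "p"
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in [self.full_mask, *self.fold_masks]:
            if m.dtype != bool:
                raise ValueError("masks must be boolean")
            if not (m == m.T).all():
                raise ValueError("mask not symmetric")
            if m.diagonal().any():
                raise ValueError("mask diagonal must be False")

    @property
    def n_folds(self) -> int:
        return len(self.fold_masks)


def _mask_from_pq(p: np.ndarray, q: np.ndarray, iu, ju, n: int, alpha: float, criterion: str) -> np.ndarray:
    vals = p if criterion == "p" else q
    mask = np.zeros((n, n), dtype=bool)
    sig = vals < alpha
    mask[iu[sig], ju[sig]] = True
    return mask | mask.T


def build_mask_family(
    adjs: list[AdjacencyMatrix],
    groups,
    alpha: float = 0.05,
    criterion: str = "p",
    welch: bool = False,
) -> MaskFamily:
    """Compute the full mask and the per-fold leave-one-out masks.

    An edge enters a mask iff its two-sample test value (uncorrected p by
    default, BH q with ``criterion="q"``) is below ``alpha`` on the subject
    set that mask is built from.
    """
    if criterion not in ("p", "q"):
        raise ValueError("criterion must be 'p' or 'q'")
    groups = np.asarray(groups)
    _check_groups(groups)
    if len(adjs) < 3:
        raise ValueError("cohort too small for leave-one-out masks")
    E, iu, ju = edge_weight_matrix(adjs)
    n = adjs[0].n_nodes
    sd = groups == GROUP_SD
    hc = groups == GROUP_HC
    if sd.sum() < 2 or hc.sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    def mask_for(subset: np.ndarray) -> np.ndarray:
        s = sd[subset]
        if s.sum() == 0 or (~s).sum() == 0:
            raise ValueError("holding out a subject emptied a group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = _group_ttest(E[subset][s], E[subset][~s], welch)
        q = bh_fdr(p) if criterion == "q" else p
        return _mask_from_pq(p, q, iu, ju, n, alpha, criterion)

    everyone = np.ones(len(adjs), dtype=bool)
    full = mask_for(everyone)
    folds = []
    for s_idx in range(len(adjs)):
        subset = everyone.copy()
        subset[s_idx] = False
        folds.append(mask_for(subset))
    return MaskFamily(
        full_mask=full,
        fold_masks=folds,
        alpha=alpha,
        criterion=criterion,
        subject_ids=[a.subject_id for a in adjs],
    )
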