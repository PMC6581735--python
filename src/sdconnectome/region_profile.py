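"""Downstream profiling: connection counts, confounder checks, node degree.

After the classifiers rank anatomical regions, the best regions are profiled
on the *full-cohort* mask: how many significant connections touch each focal
region or subregion, what their mean p-value is, and which partner regions
they reach. Two confounder analyses test whether classifier accuracy merely
tracks connection count or p-value, and a degree comparison asks which
subregions lose (or gain) weighted degree in the patient group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import AdjacencyMatrix, DegreeVector
from .edge_stats import GROUP_HC, GROUP_SD, MaskFamily, EdgeStatTable, _check_groups
from .features import FeatureSpec, feature_edges
from .parcellation import Parcellation
from .predictor import SvmConfig, loocv_evaluate

__all__ = [
    "RegionConnectionProfile",
    "profile_regions",
    "accuracy_confounder_check",
    "subsample_connections_experiment",
    "compare_subregion_degrees",
]

logger = logging.getLogger(__name__)


@dataclass
class RegionConnectionProfile:
    """Significant-connection profile of one focal region or subregion.

    ``partner_counts`` attributes each masked incident edge to the merged
    region of its non-focal endpoint; an edge internal to the focal set
    counts once, under the focal name itself.
    """

    name: str
    n_significant_connections: int
    mean_p: float  # NaN when no connections
    partner_counts: dict[str, int]


def profile_regions(
    stats_table: EdgeStatTable,
    mask: np.ndarray,
    parc: Parcellation,
    focal: list[str],
) -> list[RegionConnectionProfile]:
    """Profile each focal unit (merged region, hemispheric region, or single
    subregion name) over the masked edges incident to it."""
    if not (mask == mask.T).all():
        raise ValueError("mask must be symmetric")
    P = stats_table.p_matrix()
    labels = parc.subregion_labels
    profiles = []
    for name in focal:
        nodes = set(parc.nodes_of(name))  # KeyError for unknown names
        in_focal = np.zeros(parc.n_nodes, dtype=bool)
        in_focal[list(nodes)] = True
        iu, ju = np.triu_indices(parc.n_nodes, k=1)
        keep = mask[iu, ju] & (in_focal[iu] | in_focal[ju])
        ii, jj = iu[keep], ju[keep]
        partner_counts: dict[str, int] = {}
        ps = []
        for i, j in zip(ii, jj):
            ps.append(P[i, j])
            if in_focal[i] and in_focal[j]:
                partner = name
            else:
                other = j if in_focal[i] else i
                partner = parc.merged_region_of[labels[other]]
            partner_counts[partner] = partner_counts.get(partner, 0) + 1
        profiles.append(
            RegionConnectionProfile(
                name=name,
                n_significant_connections=int(keep.sum()),
                mean_p=float(np.mean(ps)) if ps else float("nan"),
                partner_counts=partner_counts,
            )
        )
    return profiles


@dataclass
class ConfounderCheck:
    """Pearson correlations of model accuracy with connection count and mean p."""

    r_count: float
    p_count: float
    r_meanp: float
    p_meanp: float


def accuracy_confounder_check(summary: pd.DataFrame) -> ConfounderCheck:
    """Correlate model accuracy with (a) the number of significant connections
    and (b) their mean p-value, across models.

    ``summary`` needs columns ``accuracy``, ``n_significant_connections`` and
    ``mean_p``. A constant vector makes the correlation undefined (NaN).
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 models")

    def corr(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x[ok], y[ok])
        return float(r), float(p)

    r_c, p_c = corr(summary["n_significant_connections"], summary["accuracy"])
    r_p, p_p = corr(summary["mean_p"], summary["accuracy"])
    return ConfounderCheck(r_c, p_c, r_p, p_p)


def subsample_connections_experiment(
    spec: FeatureSpec,
    masks: MaskFamily,
    adjs: list[AdjacencyMatrix],
    groups,
    cfg: SvmConfig,
    target_n: int,
    n_repeats: int,
    seed: int,
) -> tuple[float, list[float]]:
    """Mean LOOCV accuracy when the model's connections are randomly reduced.

    Each repeat draws ``target_n`` edges (without replacement) from the
    full-mask feature set and reruns the leave-one-out evaluation restricted
    to that subset (intersected per fold with the fold's own mask). Returns
    ``(mean_accuracy, per_repeat_accuracies)``; deterministic given ``seed``.
    """
    pool = feature_edges(spec, masks.full_mask)
    if not pool:
        raise ValueError("no significant connections to subsample")
    if target_n > len(pool):
        raise ValueError(f"target_n={target_n} exceeds available {len(pool)} connections")
    rng = np.random.default_rng(seed)
    accs = []
    for rep in range(n_repeats):
        idx = rng.choice(len(pool), size=target_n, replace=False)
        subset = {pool[k] for k in idx}
        report = loocv_evaluate(spec, masks, adjs, groups, cfg, edge_subset=subset)
        short = [nf for nf in report.n_features if nf < target_n]
        if short:
            logger.info(
                "repeat %d: %d fold(s) had fewer than %d connections available",
                rep, len(short), target_n,
            )
        accs.append(report.accuracy)
    return float(np.mean(accs)), accs


def compare_subregion_degrees(
    degrees: list[DegreeVector],
    groups,
    parc: Parcellation,
    focal_region: str,
    alpha: float = 0.01,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample test on weighted node degree for each subregion of a region.

    Returns one row per subregion with group mean degrees, the t statistic,
    the p-value, and a direction label (``SD<HC``, ``SD>HC`` or ``ns``)
    assigned at ``p < alpha``.
    """
    groups = np.asarray(groups)
    _check_groups(groups)
    nodes = parc.nodes_of(focal_region)
    K = np.stack([d.k for d in degrees])
    sd, hc = groups == GROUP_SD, groups == GROUP_HC
    if sd.sum() < 2 or hc.sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for i in nodes:
        t, p = stats.ttest_ind(K[sd, i], K[hc, i], equal_var=not welch)
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        mean_sd, mean_hc = K[sd, i].mean(), K[hc, i].mean()
        if p < alpha:
            direction = "SD<HC" if mean_sd < mean_hc else "SD>HC"
        else:
            direction = "ns"
        rows.append(
            {
                "subregion": parc.subregion_labels[i],
                "hemisphere": parc.hemisphere_of[parc.subregion_labels[i]],
                "mean_degree_sd": mean_sd,
                "mean_degree_hc": mean_hc,
                "t": t,
                "p_value": p,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
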