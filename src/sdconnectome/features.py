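"""Connection-feature families: anatomical regions, sliding windows, random sets.

Each feature specification names a set of subregions; the classifier's
features are the significant connections touching that set. Three families
are compared: one spec per (bilateral) anatomical region, one per
``window_size``-wide window slid row by row over the adjacency matrix, and a
collection of uniformly random subregion subsets that serve as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import AdjacencyMatrix
from .parcellation import Parcellation

__all__ = [
    "FeatureSpec",
    "anatomical_feature_specs",
    "window_feature_specs",
    "random_feature_specs",
    "feature_edges",
    "materialize_features",
]


@dataclass(frozen=True)
class FeatureSpec:
    """A named node set defining which masked edges become features.

    ``scope="incident"`` takes every masked edge with at least one endpoint in
    the node set; ``scope="within"`` only edges with both endpoints inside.
    """

    name: str
    node_set: tuple[int, ...]
    scope: str = "incident"
    family: str = "anatomical"

    def __post_init__(self) -> None:
        if not self.node_set:
            raise ValueError("node_set must be non-empty")
        if len(set(self.node_set)) != len(self.node_set):
            raise ValueError("node_set has duplicate indices")
        if min(self.node_set) < 0:
            raise ValueError("negative node index")
        if self.scope not in ("incident", "within"):
            raise ValueError("scope must be 'incident' or 'within'")


def anatomical_feature_specs(parc: Parcellation, scope: str = "incident") -> list[FeatureSpec]:
    """One spec per merged (bilateral) region, in atlas order."""
    return [
        FeatureSpec(
            name=region,
            node_set=tuple(parc.nodes_of(region)),
            scope=scope,
            family="anatomical",
        )
        for region in parc.merged_regions
    ]


def window_feature_specs(
    n_nodes: int, window_size: int, scope: str = "incident"
) -> list[FeatureSpec]:
    """``n_nodes - window_size + 1`` specs of consecutive subregions in atlas
    order (row-by-row sliding window over the adjacency matrix)."""
    if not 1 <= window_size <= n_nodes:
        raise ValueError(
            f"window_size must be in [1, n_nodes]; got {window_size} for {n_nodes} nodes"
        )
    return [
        FeatureSpec(
            name=f"window_{k + 1:03d}",
            node_set=tuple(range(k, k + window_size)),
            scope=scope,
            family="window",
        )
        for k in range(n_nodes - window_size + 1)
    ]


def random_feature_specs(
    n_nodes: int,
    set_size: int,
    n_models: int,
    seed: int,
    scope: str = "within",
) -> list[FeatureSpec]:
    """``n_models`` uniformly random subregion subsets (without replacement),
    deterministic given ``seed``.

    Unlike the anatomical and sliding-window families, the random baseline
    uses only the connections *within* each selected subregion set by
    default — a random scatter of subregions has no meaningful "incident"
    neighbourhood, and the baseline is meant to lack coherent structure.
    """
    if set_size > n_nodes:
        raise ValueError("set_size exceeds n_nodes")
    rng = np.random.default_rng(seed)
    return [
        FeatureSpec(
            name=f"random_{k + 1:03d}",
            node_set=tuple(sorted(rng.choice(n_nodes, size=set_size, replace=False))),
            scope=scope,
            family="random",
        )
        for k in range(n_models)
    ]


def feature_edges(spec: FeatureSpec, mask: np.ndarray) -> list[tuple[int, int]]:
    """Masked edges selected by the spec, in canonical (i, j), i<j lexicographic
    order — a deterministic function of (spec, mask)."""
    n = mask.shape[0]
    if max(spec.node_set) >= n:
        raise ValueError("node index outside mask dimensions")
    in_set = np.zeros(n, dtype=bool)
    in_set[list(spec.node_set)] = True
    iu, ju = np.triu_indices(n, k=1)
    if spec.scope == "incident":
        keep = mask[iu, ju] & (in_set[iu] | in_set[ju])
    else:
        keep = mask[iu, ju] & (in_set[iu] & in_set[ju])
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def materialize_features(
    spec: FeatureSpec,
    mask: np.ndarray,
    adjs: list[AdjacencyMatrix],
) -> tuple[np.ndarray, list[tuple[int, int]], list[str]]:
    """Build the subjects x features weight matrix for a spec under a mask.

    Returns ``(X, edges, names)``; an empty selection yields a (S, 0) matrix
    (no significant connections), never an error.
    """
    if not (mask == mask.T).all():
        raise ValueError("mask must be symmetric")
    edges = feature_edges(spec, mask)
    labels = adjs[0].node_labels
    names = [f"{labels[i]}—{labels[j]}" for i, j in edges]
    if not edges:
        return np.empty((len(adjs), 0)), edges, names
    ii = np.array([e[0] for e in edges])
    jj = np.array([e[1] for e in edges])
    X = np.stack([a.W[ii, jj] for a in adjs])
    return X, edges, names
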