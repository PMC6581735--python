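"""Top-level modelling interface: a study object and its fitted results.

:class:`ConnectomeStudy` bundles a cohort's networks, group labels and
parcellation; ``fit()`` runs the full biomarker pipeline — leakage-safe mask
family, the requested feature-set families, and a leave-one-out RBF-SVM
evaluation per feature set — and returns a :class:`StudyResults` carrying
every model report plus the edge statistics, with ``summary()`` as the
ranked model table and helper methods for the downstream profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SubjectRecord, cohort_parcellation, generate_cohort
from .connectome import AdjacencyMatrix, DegreeVector, RoiTimeSeries, build_networks, node_degree
from .edge_stats import EdgeStatTable, MaskFamily, build_mask_family, edgewise_ttest
from .features import (
    FeatureSpec,
    anatomical_feature_specs,
    random_feature_specs,
    window_feature_specs,
)
from .parcellation import Parcellation
from .predictor import ModelReport, SvmConfig, loocv_evaluate
from .region_profile import (
    ConfounderCheck,
    accuracy_confounder_check,
    compare_subregion_degrees,
    profile_regions,
    subsample_connections_experiment,
)

__all__ = ["ConnectomeStudy", "StudyResults"]


@dataclass
class ConnectomeStudy:
    """A cohort of weighted brain networks with group labels, ready to fit."""

    adjacencies: list[AdjacencyMatrix]
    groups: list[str]
    parcellation: Parcellation
    records: list[SubjectRecord] | None = None

    def __post_init__(self) -> None:
        if len(self.adjacencies) != len(self.groups):
            raise ValueError("one group label per subject required")
        n = self.parcellation.n_nodes
        for a in self.adjacencies:
            if a.n_nodes != n:
                raise ValueError(
                    f"subject {a.subject_id} has {a.n_nodes} nodes; parcellation has {n}"
                )

    @classmethod
    def from_timeseries(
        cls,
        ts_list: list[RoiTimeSeries],
        groups: list[str],
        parcellation: Parcellation,
        normalization: str = "subject",
        records: list[SubjectRecord] | None = None,
    ) -> "ConnectomeStudy":
        return cls(build_networks(ts_list, normalization), list(groups), parcellation, records)

    @classmethod
    def from_synthetic(cls, spec: CohortSpec, normalization: str = "subject") -> "ConnectomeStudy":
        records, ts_list = generate_cohort(spec)
        return cls.from_timeseries(
            ts_list, [r.group for r in records], cohort_parcellation(spec),
            normalization, records,
        )

    @property
    def n_subjects(self) -> int:
        return len(self.adjacencies)

    @property
    def subject_ids(self) -> list[str]:
        return [a.subject_id for a in self.adjacencies]

    def degrees(self) -> list[DegreeVector]:
        return [node_degree(a) for a in self.adjacencies]

    def fit(
        self,
        families: tuple[str, ...] = ("anatomical", "window", "random"),
        alpha: float = 0.05,
        mask_criterion: str = "p",
        window_size: int = 16,
        n_random_models: int = 100,
        random_set_size: int | None = None,
        svm_config: SvmConfig = SvmConfig(),
        seed: int = 0,
        extra_specs: list[FeatureSpec] | None = None,
        welch: bool = False,
    ) -> "StudyResults":
        """Run masks + feature families + LOOCV models; return the results.

        ``random_set_size`` defaults to ``window_size`` (the random baseline
        draws node sets the same size as the window).
        """
        masks = build_mask_family(self.adjacencies, self.groups, alpha, mask_criterion, welch)
        stats = edgewise_ttest(self.adjacencies, self.groups, welch)
        n = self.parcellation.n_nodes
        specs: list[FeatureSpec] = []
        if "anatomical" in families:
            specs += anatomical_feature_specs(self.parcellation)
        if "window" in families:
            specs += window_feature_specs(n, window_size)
        if "random" in families:
            specs += random_feature_specs(
                n, random_set_size or window_size, n_random_models, seed
            )
        specs += list(extra_specs or [])
        reports = [
            loocv_evaluate(s, masks, self.adjacencies, self.groups, svm_config)
            for s in specs
        ]
        return StudyResults(
            study=self,
            reports=reports,
            mask_family=masks,
            edge_stats=stats,
            svm_config=svm_config,
            alpha=alpha,
        )


@dataclass
class StudyResults:
    """Fitted pipeline outcome: one LOOCV report per feature model."""

    study: ConnectomeStudy
    reports: list[ModelReport]
    mask_family: MaskFamily
    edge_stats: EdgeStatTable
    svm_config: SvmConfig
    alpha: float
    _profile_cache: dict = field(default_factory=dict, repr=False)

    def report(self, model_name: str) -> ModelReport:
        for r in self.reports:
            if r.model_name == model_name:
                return r
        raise KeyError(f"no model named {model_name!r}")

    def summary(self, family: str | None = None) -> pd.DataFrame:
        """Ranked model table: accuracy, sensitivity, specificity, AUC and the
        mean per-fold feature count, sorted by accuracy (best first)."""
        rows = [
            {
                "model": r.model_name,
                "family": r.family,
                "n_features_mean": float(np.mean(r.n_features)) if r.n_features else 0.0,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "auc": r.auc,
            }
            for r in self.reports
            if family is None or r.family == family
        ]
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values("accuracy", ascending=False, kind="mergesort").reset_index(drop=True)
        return df

    def family_accuracy(self) -> pd.DataFrame:
        """Mean +/- SD of accuracy per model family."""
        df = self.summary()
        return (
            df.groupby("family")["accuracy"].agg(["mean", "std", "count"]).reset_index()
        )

    def region_profiles(self, focal: list[str] | None = None):
        """Connection profiles on the full-cohort mask (group description)."""
        focal = focal if focal is not None else self.study.parcellation.merged_regions
        key = tuple(focal)
        if key not in self._profile_cache:
            self._profile_cache[key] = profile_regions(
                self.edge_stats, self.mask_family.full_mask, self.study.parcellation, list(focal)
            )
        return self._profile_cache[key]

    def anatomical_summary_with_profiles(self) -> pd.DataFrame:
        """Anatomical model table joined with each region's connection count
        and mean p — the input to the confounder check."""
        df = self.summary(family="anatomical")
        profiles = {p.name: p for p in self.region_profiles()}
        df["n_significant_connections"] = [
            profiles[m].n_significant_connections for m in df["model"]
        ]
        df["mean_p"] = [profiles[m].mean_p for m in df["model"]]
        return df

    def confounder_check(self) -> ConfounderCheck:
        return accuracy_confounder_check(self.anatomical_summary_with_profiles())

    def compare_subregion_degrees(self, focal_region: str, alpha: float = 0.01) -> pd.DataFrame:
        return compare_subregion_degrees(
            self.study.degrees(), self.study.groups, self.study.parcellation,
            focal_region, alpha,
        )

    def subsample_connections(
        self, model_name: str, target_n: int, n_repeats: int, seed: int = 0
    ) -> tuple[float, list[float]]:
        spec = None
        for s in anatomical_feature_specs(self.study.parcellation):
            if s.name == model_name:
                spec = s
                break
        if spec is None:
            raise KeyError(f"{model_name!r} is not an anatomical region model")
        return subsample_connections_experiment(
            spec, self.mask_family, self.study.adjacencies, self.study.groups,
            self.svm_config, target_n, n_repeats, seed,
        )

    def plot_roc(self, model_names: list[str] | None = None, ax=None):
        """ROC curves of selected models (default: top five by accuracy)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        if model_names is None:
            model_names = self.summary()["model"].head(5).tolist()
        for name in model_names:
            r = self.report(name)
            xs, ys = zip(*r.roc_points)
            ax.plot(xs, ys, label=f"{name} (AUC={r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right", fontsize=8)
        return ax
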