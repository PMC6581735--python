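"""Readers and writers for the pipeline's plain-text formats.

Time series are TSV (T rows x N labelled columns, one file per subject); the
cohort manifest, parcellation table, adjacency matrices, degree vectors,
edge statistics, masks and model summaries are CSV; model reports are JSON.
Readers validate schemas strictly and report what they expected rather than
coercing silently. write -> read round-trips are identities (up to float
formatting, which uses full precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .connectome import AdjacencyMatrix, DegreeVector, RoiTimeSeries
from .edge_stats import EdgeStatTable
from .parcellation import Parcellation
from .predictor import ModelReport

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_manifest", "read_manifest",
    "write_parcellation", "read_parcellation",
    "write_adjacency", "read_adjacency",
    "write_degrees", "write_edge_stats",
    "write_mask", "read_mask",
    "write_model_report", "read_model_report",
]

_ALLOWED_GROUPS = ("SD", "HC")
_ALLOWED_SEX = ("M", "F")
_MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex", "education", "bdi"]


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.data, columns=ts.node_labels).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in columns {bad}")
    ts = RoiTimeSeries(subject_id or path.stem, df.to_numpy(float), list(df.columns))
    constant = ts.constant_columns()
    if constant:
        import warnings

        warnings.warn(
            f"{path}: constant time course in {constant}; "
            "network construction will reject these subregions",
            stacklevel=2,
        )
    return ts


def write_manifest(records: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "education": r.education,
                "bdi": r.bdi_score,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df[_MANIFEST_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: manifest contains missing values")
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if row.group not in _ALLOWED_GROUPS:
            raise ValueError(
                f"{path} line {line}: unknown group {row.group!r}; "
                f"allowed: {list(_ALLOWED_GROUPS)}"
            )
        if row.sex not in _ALLOWED_SEX:
            raise ValueError(
                f"{path} line {line}: unknown sex {row.sex!r}; "
                f"allowed: {list(_ALLOWED_SEX)}"
            )
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            group=r.group,
            age=float(r.age),
            sex=r.sex,
            education=float(r.education),
            bdi_score=float(r.bdi),
        )
        for r in df.itertuples(index=False)
    ]


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    parc.to_frame().to_csv(path, index=False)


def read_parcellation(path: str | Path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path))


def write_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    pd.DataFrame(adj.W, index=adj.node_labels, columns=adj.node_labels).to_csv(path)


def read_adjacency(path: str | Path, subject_id: str | None = None) -> AdjacencyMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return AdjacencyMatrix(subject_id or path.stem, df.to_numpy(float), list(df.columns))


def write_degrees(degrees: list[DegreeVector], path: str | Path) -> None:
    rows = []
    for d in degrees:
        for lab, k in zip(d.node_labels, d.k):
            rows.append({"subject_id": d.subject_id, "subregion": lab, "degree": k})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_edge_stats(stats: EdgeStatTable, path: str | Path) -> None:
    stats.table.to_csv(path, index=False)


def write_mask(mask: np.ndarray, node_labels: list[str], path: str | Path) -> None:
    """Mask as an edge list CSV (upper triangle only)."""
    iu, ju = np.triu_indices(mask.shape[0], k=1)
    keep = mask[iu, ju]
    pd.DataFrame(
        {
            "i": iu[keep],
            "j": ju[keep],
            "node_i": [node_labels[k] for k in iu[keep]],
            "node_j": [node_labels[k] for k in ju[keep]],
        }
    ).to_csv(path, index=False)


def read_mask(path: str | Path, n_nodes: int) -> np.ndarray:
    df = pd.read_csv(path)
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    if len(df):
        mask[df["i"].to_numpy(), df["j"].to_numpy()] = True
    return mask | mask.T


def write_model_report(report: ModelReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def read_model_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
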