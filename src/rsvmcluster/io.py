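"""Delimited-text I/O for every artifact the pipeline reads or writes.

All tabular formats are TSV.  Time series are T x N with a header row
of region labels; connectivity matrices are N x N with region labels as
header; feature tables carry descriptor-named columns plus a leading
``subject_id`` column; label files are two columns (subject_id, label).
Fitted clusters are serialized with joblib into a single archive.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .ensemble import RandomSVMCluster
from .features import FeatureIndexMap, LabeledDataset
from .graph import ConnectivityMatrix, ROITimeSeries


def read_time_series(path: str | Path) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(df.to_numpy(dtype=float), list(df.columns))


def write_time_series(ts: ROITimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_ids).to_csv(
        path, sep="\t", index=False
    )


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(conn.values, columns=conn.region_ids).to_csv(
        path, sep="\t", index=False
    )


def write_feature_table(
    ds: LabeledDataset,
    fmap: FeatureIndexMap,
    path: str | Path,
    region_ids: Sequence[str] | None = None,
) -> None:
    df = pd.DataFrame(
        ds.X, columns=fmap.feature_names(list(region_ids) if region_ids else None)
    )
    df.insert(0, "subject_id", ds.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path, labels: dict[str, int]) -> LabeledDataset:
    """Read a feature table and join labels by subject id."""
    df = pd.read_csv(path, sep="\t")
    ids = df.pop("subject_id").tolist()
    y = np.array([labels[s] for s in ids], dtype=int)
    return LabeledDataset(df.to_numpy(dtype=float), y, ids)


def write_labels(
    subject_ids: Sequence[str], labels: Sequence[int], path: str | Path
) -> None:
    pd.DataFrame({"subject_id": list(subject_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["subject_id"], df["label"].astype(int)))


def save_cluster(cluster: RandomSVMCluster, path: str | Path) -> None:
    joblib.dump(cluster, path)


def load_cluster(path: str | Path) -> RandomSVMCluster:
    return joblib.load(path)
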