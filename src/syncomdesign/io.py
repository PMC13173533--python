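"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as TSV (rows = strain IDs, columns = EC-labeled
enzyme classes, integer counts), labels and time series as CSV with header
rows, pathway maps and planted models as JSON, and graphs as typed edge
lists (TSV) or GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .assay import AssaySeries, AbundanceTable
from .network import MetabolicGraph

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_labels",
    "read_labels",
    "write_pathway_map",
    "read_pathway_map",
    "write_series",
    "read_series",
    "read_abundance_table",
    "write_abundance_table",
    "write_edge_list",
    "write_graphml",
    "write_features",
]


def write_count_matrix(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index_label="strain")


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain")
    return df.astype(int)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index_label="strain")


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="strain")


def write_pathway_map(pathway_map: dict, path) -> None:
    Path(path).write_text(json.dumps(pathway_map, indent=1))


def read_pathway_map(path) -> dict:
    return json.loads(Path(path).read_text())


def write_series(series: AssaySeries, path) -> None:
    pd.DataFrame(
        {"time_days": series.times, "mean": series.mean, "sd": series.sd,
         "n": series.n_reps, "unit": series.unit}
    ).to_csv(path, index=False)


def read_series(path) -> AssaySeries:
    df = pd.read_csv(path)
    unit = str(df["unit"].iloc[0]) if "unit" in df else "mg/L"
    n = int(df["n"].iloc[0]) if "n" in df else 1
    sd = df["sd"].to_numpy() if "sd" in df else np.zeros(len(df))
    return AssaySeries(
        times=df["time_days"].to_numpy(), mean=df["mean"].to_numpy(), sd=sd,
        n_reps=n, unit=unit,
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = pd.DataFrame(table.abundances, columns=table.strain_ids or None)
    df.insert(0, "time_days", table.times)
    df.to_csv(path, index=False)


def read_abundance_table(path) -> AbundanceTable:
    df = pd.read_csv(path)
    times = df.pop("time_days").to_numpy()
    return AbundanceTable(times=times, abundances=df.to_numpy(), strain_ids=list(df.columns))


def write_edge_list(mg: MetabolicGraph, path) -> None:
    mg.to_edge_list().to_csv(path, sep="\t", index=False)


def write_graphml(mg: MetabolicGraph, path) -> None:
    nx.write_graphml(mg.graph, path)


def write_features(feature_map: dict, path) -> None:
    """Node features as CSV: node ID column + one column per dimension."""
    nodes = sorted(feature_map, key=str)
    arr = np.vstack([feature_map[n] for n in nodes])
    df = pd.DataFrame(arr, columns=[f"f{i}" for i in range(arr.shape[1])])
    df.insert(0, "node", nodes)
    df.to_csv(path, index=False)
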