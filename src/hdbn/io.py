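"""Text I/O: matrix TSVs, manifests, configs, circuit files, graph export.

All tables are tab-separated UTF-8 with a header row; missing values
are written as ``NA``.  Floats are written with repr-round-trip
precision so write -> read -> write is byte-stable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .circuits import CircuitDefinition
from .connectome import Connectome, WeightedGraphView
from .parcellation import RegionTable

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_manifest",
    "read_manifest",
    "load_config",
    "save_config",
    "read_circuit_file",
    "write_circuit_file",
    "to_networkx",
    "write_graphml",
    "write_table",
]

NA = "NA"
FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy TSV with NA for missing values and stable float formatting."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=FLOAT_FORMAT)


def write_matrix_tsv(path, matrix: np.ndarray, labels: Sequence[str]) -> None:
    """Write a labelled square matrix TSV (labels in header row and first column)."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT)


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix TSV back into (matrix, labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix {path!r} row labels do not match column labels")
    return df.to_numpy(dtype=float), list(df.index)


def write_manifest(path, rows: pd.DataFrame) -> None:
    """Write an animal manifest TSV (animal_id, group, matrix_path, ...)."""
    required = {"animal_id", "group", "matrix_path"}
    if not required.issubset(rows.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    write_table(rows, path)


def read_manifest(path, require_both_groups: bool = True) -> pd.DataFrame:
    """Read and validate an animal manifest TSV."""
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    required = {"animal_id", "group", "matrix_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path!r} needs columns {sorted(required)}")
    if df["animal_id"].duplicated().any():
        dup = sorted(df.loc[df["animal_id"].duplicated(), "animal_id"])
        raise ValueError(f"duplicate animal ids in manifest: {dup}")
    bad = set(df["group"]) - {"WT", "KO"}
    if bad:
        raise ValueError(f"manifest groups must be WT or KO, got {sorted(bad)}")
    if require_both_groups and len(set(df["group"])) < 2:
        raise ValueError("manifest must contain both WT and KO animals")
    return df


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path!r} must be a mapping")
    return cfg


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_circuit_file(path) -> CircuitDefinition:
    """Read a circuit definition from a YAML file (name, nodes, pairs)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CircuitDefinition(
        name=data["name"],
        nodes=tuple(data["nodes"]),
        pairs=tuple((a, b) for a, b in data["pairs"]),
    )


def write_circuit_file(path, circuit: CircuitDefinition) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"name": circuit.name, "nodes": list(circuit.nodes),
                        "pairs": [list(p) for p in circuit.pairs]}, fh,
                       sort_keys=False)


def to_networkx(view: WeightedGraphView | Connectome) -> nx.Graph:
    """Convert a view or connectome to an undirected weighted networkx graph."""
    if isinstance(view, Connectome):
        w, labels = view.counts, view.labels
    else:
        w, labels = view.weights, view.labels
    g = nx.Graph()
    g.add_nodes_from(labels)
    iu, ju = np.triu_indices(len(labels), k=1)
    for i, j in zip(iu, ju):
        if w[i, j] > 0:
            g.add_edge(labels[i], labels[j], weight=float(w[i, j]))
    return g


def write_graphml(path, view: WeightedGraphView | Connectome) -> None:
    nx.write_graphml(to_networkx(view), path)
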