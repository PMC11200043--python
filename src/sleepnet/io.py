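"""Reading questionnaire CSVs and writing/reading network artifacts.

Networks round-trip through either a JSON edge list (zero-weight pairs
omitted, node count and metadata recorded) or GraphML; both store weights at
full double precision (shortest round-trip decimal representation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd

from .datatypes import (BinarySymptomTable, EstimationConfig, IsingModel,
                        NetworkArtifact, potential_edge_count)

logger = logging.getLogger(__name__)

__all__ = ["VariableSpec", "read_symptom_csv", "write_network", "read_network"]


@dataclass(frozen=True)
class VariableSpec:
    """Which CSV columns are analysis variables, their blocks and recodings.

    ``recode`` maps column name -> {raw value -> 0/1}; raw values are
    compared as strings, so ``{"yes": 1, "no": 0}`` and ``{"2": 0}`` both
    work regardless of the CSV's original dtype.
    """

    variables: tuple[str, ...]
    blocks: tuple[str, ...] = ()
    recode: Mapping[str, Mapping[str, int]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        blocks = tuple(self.blocks)
        if blocks and len(blocks) != len(self.variables):
            raise ValueError("blocks must be empty or match variables in length")
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        variables = d["variables"]
        if isinstance(variables, Mapping):  # name -> block
            names = tuple(variables)
            blocks = tuple(str(variables[k]) for k in names)
        else:
            names = tuple(variables)
            blocks = tuple(d.get("blocks", ()))
        return cls(names, blocks, d.get("recode", {}))


def read_symptom_csv(path, variable_spec: VariableSpec | Mapping,
                     group_columns: Sequence[str] = ()) -> BinarySymptomTable:
    """Load a respondents × symptoms CSV into a validated table.

    Rows with missing values in any analysis column are dropped
    (complete-case) and the drop count logged. A non-binary value in a
    symptom column without a recoding rule raises, naming column and row.
    """
    if not isinstance(variable_spec, VariableSpec):
        variable_spec = VariableSpec.from_dict(variable_spec)
    df = pd.read_csv(path)
    missing_cols = [c for c in (*variable_spec.variables, *group_columns)
                    if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")

    analysis = list(variable_spec.variables)
    n_raw = len(df)
    df = df.dropna(subset=analysis + list(group_columns))
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d of %d rows with missing values in analysis "
                    "columns", n_dropped, n_raw)
    if not len(df):
        raise ValueError("no complete rows remain after dropping missing values")

    values = np.empty((len(df), len(analysis)))
    for j, col in enumerate(analysis):
        raw = df[col].to_numpy()
        rule = {str(k): int(v) for k, v in
                dict(variable_spec.recode.get(col, {})).items()}
        col_vals = np.empty(len(raw))
        for i, v in enumerate(raw):
            s = _canonical_str(v)
            if s in rule:
                col_vals[i] = rule[s]
            elif s in ("0", "1"):
                col_vals[i] = float(s)
            else:
                raise ValueError(
                    f"non-binary value {v!r} in column {col!r} "
                    f"(CSV data row {df.index[i] + 1}) with no recoding rule")
        values[:, j] = col_vals
    groups = {c: df[c].to_numpy() for c in group_columns}
    return BinarySymptomTable(values, tuple(analysis), variable_spec.blocks,
                              groups)


def _canonical_str(v) -> str:
    """'1', 1, 1.0 and '1.0' all canonicalize to '1'."""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)) and float(v).is_integer():
        return str(int(v))
    s = str(v).strip()
    try:
        f = float(s)
        if f.is_integer():
            return str(int(f))
    except ValueError:
        pass
    return s


def _artifact_metadata(artifact: NetworkArtifact) -> dict:
    config = (dataclasses.asdict(artifact.config)
              if artifact.config is not None else None)
    return {
        "group_id": artifact.group_id,
        "n_used": artifact.n_used,
        "p": artifact.model.p,
        "n_potential_edges": potential_edge_count(artifact.model.p),
        "config": config,
    }


def write_network(artifact: NetworkArtifact, path, format: str = "json") -> None:
    """Write a network artifact as a JSON edge list or GraphML.

    Round-trip safe: :func:`read_network` reproduces Ω and τ exactly.
    Zero-weight pairs are omitted from the edge list; the node count (hence
    the number of potential pairs) is recorded in the metadata.
    """
    path = Path(path)
    if format == "json":
        payload = {
            "format": "sleepnet-network/1",
            **_artifact_metadata(artifact),
            "nodes": [
                {"id": name, "block": block, "threshold": float(tau)}
                for name, block, tau in zip(artifact.variable_names,
                                            artifact.block_labels,
                                            artifact.model.thresholds)
            ],
            "edges": [
                {"source": artifact.variable_names[i],
                 "target": artifact.variable_names[j],
                 "weight": w}
                for i, j, w in artifact.model.edge_list()
            ],
        }
        if artifact.layout is not None:
            payload["layout"] = artifact.layout.tolist()
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif format == "graphml":
        g = nx.Graph()
        meta = _artifact_metadata(artifact)
        g.graph["group_id"] = meta["group_id"]
        g.graph["n_used"] = meta["n_used"]
        g.graph["n_potential_edges"] = meta["n_potential_edges"]
        g.graph["config"] = json.dumps(meta["config"], sort_keys=True)
        for i, (name, block, tau) in enumerate(zip(artifact.variable_names,
                                                   artifact.block_labels,
                                                   artifact.model.thresholds)):
            attrs = {"block": block, "threshold": float(tau), "order": i}
            if artifact.layout is not None:
                attrs["x"] = float(artifact.layout[i, 0])
                attrs["y"] = float(artifact.layout[i, 1])
            g.add_node(name, **attrs)
        for i, j, w in artifact.model.edge_list():
            g.add_edge(artifact.variable_names[i], artifact.variable_names[j],
                       weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError("format must be 'json' or 'graphml'")


def read_network(path) -> NetworkArtifact:
    """Read a network written by :func:`write_network` (format sniffed)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return _read_network_json(json.loads(text))
    return _read_network_graphml(path)


def _read_network_json(payload: dict) -> NetworkArtifact:
    names = [nd["id"] for nd in payload["nodes"]]
    blocks = [nd["block"] for nd in payload["nodes"]]
    tau = np.array([nd["threshold"] for nd in payload["nodes"]])
    p = len(names)
    index = {name: i for i, name in enumerate(names)}
    omega = np.zeros((p, p))
    for e in payload["edges"]:
        i, j = index[e["source"]], index[e["target"]]
        omega[i, j] = omega[j, i] = e["weight"]
    config = (EstimationConfig(**payload["config"])
              if payload.get("config") else None)
    layout = np.array(payload["layout"]) if "layout" in payload else None
    return NetworkArtifact(IsingModel(tau, omega), payload["group_id"],
                           payload["n_used"], config, tuple(names),
                           tuple(blocks), layout)


def _read_network_graphml(path: Path) -> NetworkArtifact:
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes(data=True), key=lambda kv: kv[1]["order"])
    names = [name for name, _ in nodes]
    blocks = [attrs["block"] for _, attrs in nodes]
    tau = np.array([attrs["threshold"] for _, attrs in nodes])
    p = len(names)
    index = {name: i for i, name in enumerate(names)}
    omega = np.zeros((p, p))
    for u, v, attrs in g.edges(data=True):
        i, j = index[u], index[v]
        omega[i, j] = omega[j, i] = attrs["weight"]
    config_json = g.graph.get("config")
    config = (EstimationConfig(**json.loads(config_json))
              if config_json and config_json != "null" else None)
    layout = None
    if nodes and "x" in nodes[0][1]:
        layout = np.array([[attrs["x"], attrs["y"]] for _, attrs in nodes])
    return NetworkArtifact(IsingModel(tau, omega), g.graph.get("group_id", "all"),
                           int(g.graph.get("n_used", 0)), config,
                           tuple(names), tuple(blocks), layout)
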