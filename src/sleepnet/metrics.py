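"""Node-level network inferences: centrality, predictability, layout.

Centrality follows the conventions of weighted symptom networks: strength is
the sum of absolute edge weights at a node, expected influence the signed
sum; closeness and betweenness are shortest-path centralities where an edge
of weight ω has length 1/|ω| (stronger association = shorter path).
Predictability measures how well a node is predicted by its estimated
neighborhood, on a [0, 1] scale.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import networkx as nx
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.exceptions import ConvergenceWarning

from .datatypes import BinarySymptomTable, IsingModel

__all__ = ["strength", "global_strength", "expected_influence",
           "path_centralities", "centrality_table", "standardize",
           "predictability", "fr_layout"]


def strength(model: IsingModel) -> np.ndarray:
    """Per-node strength: Σ_{j≠i} |ω_ij|."""
    return np.abs(model.weights).sum(axis=1)


def global_strength(model: IsingModel) -> float:
    """Σ_{i<j} |ω_ij| — half the total of node strengths."""
    return float(np.abs(model.weights).sum() / 2.0)


def expected_influence(model: IsingModel) -> np.ndarray:
    """Per-node signed sum Σ_{j≠i} ω_ij (negative edges keep their sign)."""
    return model.weights.sum(axis=1)


def _length_graph(model: IsingModel) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(model.p))
    for i, j, w in model.edge_list():
        g.add_edge(i, j, weight=w, length=1.0 / abs(w))
    return g


def path_centralities(model: IsingModel) -> tuple[np.ndarray, np.ndarray]:
    """Closeness and betweenness on edge lengths 1/|ω|.

    closeness_i = (r_i − 1)/(p − 1) · 1/Σ_j d(i, j), summing over the r_i
    nodes reachable from i (0 for isolates) — the component-size correction
    keeps the measure comparable across disconnected graphs. Betweenness
    counts fractional shares of shortest paths passing through each node
    (unnormalized).
    """
    p = model.p
    g = _length_graph(model)
    closeness = np.zeros(p)
    for i in range(p):
        dists = nx.single_source_dijkstra_path_length(g, i, weight="length")
        total = sum(d for node, d in dists.items() if node != i)
        r = len(dists)  # includes i itself
        if r > 1 and total > 0:
            closeness[i] = (r - 1) / (p - 1) / total
    bet = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([bet[i] for i in range(p)])
    return closeness, betweenness


def centrality_table(model: IsingModel,
                     variable_names: Sequence[str] | None = None) -> pd.DataFrame:
    """All four centrality indices as a DataFrame indexed by node name."""
    names = list(variable_names) if variable_names is not None else [
        f"V{i + 1}" for i in range(model.p)]
    closeness, betweenness = path_centralities(model)
    return pd.DataFrame(
        {
            "strength": strength(model),
            "closeness": closeness,
            "betweenness": betweenness,
            "expected_influence": expected_influence(model),
        },
        index=pd.Index(names, name="node"),
    )


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z scores (mean 0, SD 1); constant columns map to zeros."""
    if len(table) < 2:
        raise ValueError("need at least 2 nodes to standardize")
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=np.float64)
        sd = x.std(ddof=0)
        if sd == 0.0:
            warnings.warn(f"column {col!r} is constant; z scores set to 0",
                          RuntimeWarning)
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def _node_predictability(y: np.ndarray, X_nbr: np.ndarray | None,
                         method: str) -> float:
    ybar = y.mean()
    if X_nbr is None or X_nbr.shape[1] == 0 or ybar in (0.0, 1.0):
        phat = np.full_like(y, ybar)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # C=inf: unpenalized maximum-likelihood refit
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
            clf.fit(X_nbr, y)
        phat = clf.predict_proba(X_nbr)[:, 1]
    if method == "r2":
        brier = np.mean((phat - y) ** 2)
        brier0 = np.mean((ybar - y) ** 2)
        value = 0.0 if brier0 == 0.0 else 1.0 - brier / brier0
    elif method == "normalized_accuracy":
        acc = np.mean((phat > 0.5) == y)
        acc0 = max(ybar, 1.0 - ybar)
        value = 0.0 if acc0 == 1.0 else (acc - acc0) / (1.0 - acc0)
    else:
        raise ValueError("method must be 'r2' or 'normalized_accuracy'")
    return float(np.clip(value, 0.0, 1.0))


def predictability(table: BinarySymptomTable, model: IsingModel,
                   method: str = "r2") -> pd.DataFrame:
    """Nodewise predictability from the estimated neighborhood, in [0, 1].

    Each node is refit by *unpenalized* logistic regression on its selected
    neighbors. ``r2`` (default) is the Brier-score analogue of explained
    variance, 1 − Brier(model)/Brier(intercept only); ``normalized_accuracy``
    is the accuracy gain over the marginal classifier rescaled by its
    headroom. Both are clipped to [0, 1]; an empty neighborhood scores 0.
    """
    if table.p != model.p:
        raise ValueError(
            f"data has p={table.p} columns but model has p={model.p} nodes")
    values = []
    for i in range(model.p):
        nbrs = np.flatnonzero(model.weights[i] != 0.0)
        X_nbr = table.values[:, nbrs] if nbrs.size else None
        values.append(_node_predictability(table.values[:, i], X_nbr, method))
    return pd.DataFrame({"predictability": values, "method": method},
                        index=pd.Index(table.variable_names, name="node"))


def fr_layout(model: IsingModel, seed: int = 0,
              iterations: int = 100) -> np.ndarray:
    """Fruchterman–Reingold coordinates with |ω| as attraction weights.

    Deterministic given ``seed``; coordinates min-max scaled to the unit box
    (degenerate axes centered at 0.5).
    """
    g = nx.Graph()
    g.add_nodes_from(range(model.p))
    for i, j, w in model.edge_list():
        g.add_edge(i, j, weight=abs(w))
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    coords = np.array([pos[i] for i in range(model.p)], dtype=np.float64)
    span = coords.max(axis=0) - coords.min(axis=0)
    out = np.empty_like(coords)
    for axis in range(2):
        if span[axis] > 0:
            out[:, axis] = (coords[:, axis] - coords[:, axis].min()) / span[axis]
        else:
            out[:, axis] = 0.5
    return out
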