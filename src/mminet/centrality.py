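"""Centrality indices on a fitted network.

Three standard indices for weighted psychometric-style networks:

* strength — the sum of absolute edge weights at a node;
* expected influence — the signed sum (identical to strength when every
  edge is positive; lower when a node carries negative edges);
* betweenness — the (fractionally credited) number of shortest paths
  between other node pairs passing through the node, with edge lengths
  1/|w| so stronger edges are shorter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .mrf import NetworkModel

__all__ = [
    "strength",
    "expected_influence",
    "betweenness",
    "centrality_table",
    "plot_centrality",
    "METRICS",
]

METRICS = ("strength", "expected_influence", "betweenness")


def strength(model: NetworkModel) -> np.ndarray:
    """Per-node absolute edge-weight sum."""
    return np.abs(model.weights).sum(axis=1)


def expected_influence(model: NetworkModel) -> np.ndarray:
    """Per-node signed edge-weight sum (one-step expected influence)."""
    return model.weights.sum(axis=1)


def _graph(model: NetworkModel) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(model.p))
    iu, ju = np.nonzero(np.triu(model.weights, k=1))
    for i, j in zip(iu, ju):
        G.add_edge(int(i), int(j), length=1.0 / abs(model.weights[i, j]))
    return G


def betweenness(model: NetworkModel) -> np.ndarray:
    """Weighted betweenness with edge lengths 1/|w| (Brandes convention:
    tied geodesics share credit fractionally; absent edges are
    non-adjacent)."""
    bc = nx.betweenness_centrality(_graph(model), weight="length", normalized=False)
    return np.array([bc[i] for i in range(model.p)])


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(model: NetworkModel) -> pd.DataFrame:
    """Raw and z-standardized strength / expected influence / betweenness,
    ordered as the model's nodes.

    When an index is constant across nodes its z-column is set to 0 and the
    ``degenerate_z`` attribute lists the affected indices.
    """
    s, ei, b = strength(model), expected_influence(model), betweenness(model)
    table = pd.DataFrame(
        {
            "node": list(model.node_names),
            "strength": s,
            "expected_influence": ei,
            "betweenness": b,
            "z_strength": _z(s),
            "z_expected_influence": _z(ei),
            "z_betweenness": _z(b),
        }
    )
    table.attrs["degenerate_z"] = [
        m for m, v in zip(METRICS, (s, ei, b)) if v.std() == 0
    ]
    return table


def metric_vector(model: NetworkModel, metric: str) -> np.ndarray:
    """One centrality (or flattened edge-weight) vector, for stability work."""
    if metric == "strength":
        return strength(model)
    if metric == "expected_influence":
        return expected_influence(model)
    if metric == "betweenness":
        return betweenness(model)
    if metric == "edge_weight":
        iu, ju = np.triu_indices(model.p, k=1)
        return model.weights[iu, ju]
    raise ValueError(f"unknown metric {metric!r}")


def plot_centrality(table: pd.DataFrame, ax=None, standardized: bool = True):
    """Simple line plot of the three indices across nodes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(table))))
    cols = (
        ["z_strength", "z_betweenness", "z_expected_influence"]
        if standardized
        else ["strength", "betweenness", "expected_influence"]
    )
    for col in cols:
        ax.plot(table[col], range(len(table)), marker="o", ms=3, label=col)
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels(table["node"])
    ax.invert_yaxis()
    ax.legend(fontsize=7)
    ax.set_xlabel("centrality" + (" (z)" if standardized else ""))
    return ax
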