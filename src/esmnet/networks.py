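"""Significance-masked temporal and contemporaneous network assembly."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class TemporalNetwork:
    """Directed lag-1 network: ``weights[i, j]`` is the fixed-effect
    coefficient of variable i at day t-1 on variable j at day t; the diagonal
    holds autocorrelations (self-loops)."""

    weights: np.ndarray
    p_values: np.ndarray
    alpha: float
    variable_names: list[str]
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.significant is None:
            self.significant = self.p_values < self.alpha
        self.significant = np.asarray(self.significant, dtype=bool)
        if self.weights.shape != self.p_values.shape or self.weights.shape != self.significant.shape:
            raise ValueError("weights, p_values and significant must share a shape")
        if (self.significant & ~(self.p_values < self.alpha)).any():
            raise ValueError("mask inconsistency: significant entry with p >= alpha")

    @property
    def n_vars(self) -> int:
        return self.weights.shape[0]

    @property
    def masked_weights(self) -> np.ndarray:
        """Weights with non-significant entries zeroed (the reported network)."""
        return np.where(self.significant, self.weights, 0.0)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, src in enumerate(self.variable_names):
            for j, dst in enumerate(self.variable_names):
                rows.append(
                    {
                        "from": src,
                        "to": dst,
                        "weight": self.weights[i, j],
                        "p_value": self.p_values[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_graph(self, masked: bool = True) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variable_names)
        w = self.masked_weights if masked else self.weights
        for i, src in enumerate(self.variable_names):
            for j, dst in enumerate(self.variable_names):
                if masked and not self.significant[i, j]:
                    continue
                g.add_edge(src, dst, weight=float(w[i, j]), p_value=float(self.p_values[i, j]))
        return g


@dataclass
class ContemporaneousNetwork:
    """Undirected same-day partial-correlation network (zero diagonal)."""

    weights: np.ndarray
    significant: np.ndarray
    alpha: float
    variable_names: list[str]
    coef_matrix: np.ndarray | None = None
    p_value_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("contemporaneous weights must be symmetric")
        if (self.significant != self.significant.T).any():
            raise ValueError("significance mask must be symmetric")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise ValueError("diagonal must be zero")
        if (np.abs(self.weights) > 1.0 + 1e-12).any():
            raise ValueError("partial correlations must lie in [-1, 1]")

    @property
    def n_vars(self) -> int:
        return self.weights.shape[0]

    @property
    def masked_weights(self) -> np.ndarray:
        return np.where(self.significant, self.weights, 0.0)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        p = self.n_vars
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "from": self.variable_names[i],
                        "to": self.variable_names[j],
                        "weight": self.weights[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_graph(self, masked: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.variable_names)
        p = self.n_vars
        for i in range(p):
            for j in range(i + 1, p):
                if masked and not self.significant[i, j]:
                    continue
                g.add_edge(
                    self.variable_names[i],
                    self.variable_names[j],
                    weight=float(self.weights[i, j]),
                )
        return g


def build_temporal_network(fits, alpha: float = 0.05) -> TemporalNetwork:
    """Assemble the directed lagged-effect matrix from node-wise fits.

    Column j of ``weights`` is node j's coefficient vector; the diagonal
    (autocorrelation) is retained as a self-loop candidate.
    """
    p = len(fits)
    for j, fit in enumerate(fits):
        if not hasattr(fit, "fixed_coefs"):
            raise ValueError(f"missing or failed fit for node {j}: {fit!r}")
        if len(fit.fixed_coefs) != p:
            raise ValueError("each fit must carry one coefficient per variable")
    weights = np.column_stack([f.fixed_coefs for f in fits])
    p_values = np.column_stack([f.p_values for f in fits])
    names = [f.target_name for f in fits]
    return TemporalNetwork(weights=weights, p_values=p_values, alpha=alpha, variable_names=names)


def count_significant_edges(net: TemporalNetwork, include_auto: bool = False) -> tuple[int, float]:
    """Count significant edges and their proportion of candidate positions.

    Excluding autocorrelations there are p(p-1) candidate directed edges;
    including them, p^2.  Returns (count, raw proportion).
    """
    p = net.n_vars
    mask = net.significant.copy()
    if include_auto:
        total = p * p
    else:
        np.fill_diagonal(mask, False)
        total = p * (p - 1)
    count = int(mask.sum())
    return count, count / total


def candidate_edge_count(n_vars: int, include_auto: bool = False) -> int:
    """Number of candidate directed lag-1 edge positions."""
    return n_vars * n_vars if include_auto else n_vars * (n_vars - 1)


def find_feedback_loops(net: TemporalNetwork, max_length: int = 3) -> list[dict]:
    """All simple directed cycles of length 2..max_length over significant
    edges (self-loops excluded), deduplicated up to rotation and ordered by
    their smallest node index."""
    if max_length not in (2, 3):
        raise ValueError("max_length must be 2 or 3")
    mask = net.significant.copy()
    np.fill_diagonal(mask, False)
    g = nx.from_numpy_array(mask.astype(int), create_using=nx.DiGraph)
    loops = []
    for cycle in nx.simple_cycles(g, length_bound=max_length):
        if len(cycle) < 2:
            continue
        k = int(np.argmin(cycle))
        cycle = cycle[k:] + cycle[:k]
        weights = [
            float(net.weights[cycle[t], cycle[(t + 1) % len(cycle)]]) for t in range(len(cycle))
        ]
        loops.append(
            {
                "nodes": [net.variable_names[i] for i in cycle],
                "indices": list(cycle),
                "weights": weights,
            }
        )
    loops.sort(key=lambda item: (len(item["indices"]), item["indices"]))
    return loops


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)


def export_node_link_json(graph: nx.Graph, path: str | Path) -> None:
    import json

    data = nx.node_link_data(graph, edges="links")
    Path(path).write_text(json.dumps(data, indent=2))
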