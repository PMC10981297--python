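"""Raw-score strength centralities for temporal and contemporaneous networks.

Out-/In-strength sum absolute significant edge weights leaving/entering a
node in the temporal network, excluding the self-loop (autocorrelation);
contemporaneous strength sums absolute significant incident edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from esmnet.networks import ContemporaneousNetwork, TemporalNetwork


@dataclass
class CentralityTable:
    """Per-variable raw strength scores."""

    variable_names: list[str]
    out_strength: np.ndarray
    in_strength: np.ndarray
    contemporaneous_strength: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "variable": self.variable_names,
            "out_strength": self.out_strength,
            "in_strength": self.in_strength,
        }
        if self.contemporaneous_strength is not None:
            data["contemporaneous_strength"] = self.contemporaneous_strength
        return pd.DataFrame(data)


def _offdiag_masked_abs(net: TemporalNetwork, masked: bool) -> np.ndarray:
    w = np.abs(net.masked_weights if masked else net.weights).copy()
    np.fill_diagonal(w, 0.0)
    return w


def out_strength(net: TemporalNetwork, masked: bool = True) -> np.ndarray:
    """Sum of |weight| over significant outgoing edges, self-loop excluded."""
    return _offdiag_masked_abs(net, masked).sum(axis=1)


def in_strength(net: TemporalNetwork, masked: bool = True) -> np.ndarray:
    """Sum of |weight| over significant incoming edges, self-loop excluded."""
    return _offdiag_masked_abs(net, masked).sum(axis=0)


def contemporaneous_strength(net: ContemporaneousNetwork, masked: bool = True) -> np.ndarray:
    """Sum of |weight| over significant incident undirected edges."""
    w = np.abs(net.masked_weights if masked else net.weights)
    if not np.allclose(w, w.T):
        raise ValueError("contemporaneous network must be symmetric")
    return w.sum(axis=1)


def centrality_table(
    temporal: TemporalNetwork,
    contemporaneous: ContemporaneousNetwork | None = None,
    masked: bool = True,
) -> CentralityTable:
    return CentralityTable(
        variable_names=list(temporal.variable_names),
        out_strength=out_strength(temporal, masked),
        in_strength=in_strength(temporal, masked),
        contemporaneous_strength=(
            contemporaneous_strength(contemporaneous, masked) if contemporaneous is not None else None
        ),
    )


def rank_centrality(table: CentralityTable, index: str = "out") -> pd.DataFrame:
    """Variables ordered by descending strength; ties keep input order and
    are flagged."""
    key = {
        "out": "out_strength",
        "in": "in_strength",
        "contemporaneous": "contemporaneous_strength",
    }.get(index)
    if key is None:
        raise ValueError("index must be 'out', 'in' or 'contemporaneous'")
    frame = table.to_frame()
    if key not in frame.columns:
        raise ValueError(f"{key} not computed in this table")
    frame = frame.reset_index(names="_order")
    frame = frame.sort_values([key, "_order"], ascending=[False, True], kind="stable")
    values = frame[key].to_numpy()
    tied = np.isin(values, values[pd.Series(values).duplicated(keep=False).to_numpy()])
    out = frame[["variable", key]].copy()
    out["tied"] = tied
    return out.reset_index(drop=True)


def plot_strength(table: CentralityTable, path=None):
    """Optional bar chart of the strength indices (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = table.to_frame().set_index("variable")
    ax = frame.plot.barh(figsize=(7, 0.6 * len(frame) + 1))
    ax.set_xlabel("strength (raw score)")
    ax.invert_yaxis()
    fig = ax.get_figure()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax
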