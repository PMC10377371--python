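"""Spearman correlation heatmaps and thresholded correlation networks.

Rank correlation is computed pairwise (pairwise-complete observations,
average ranks for ties) over the perfusion parameters and clinical
covariates of the pooled assessment points.  The correlation network keeps
an edge wherever |rho| exceeds a threshold (0.2 by default), signed
positive ("blue") or negative ("red"); binary covariates enter as 0/1,
for which Spearman rho against a continuous variable coincides with the
rank-biserial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationNetwork",
    "spearman_matrix",
    "build_network",
    "to_networkx",
    "export_graphml",
    "plot_heatmap",
    "plot_network",
]


@dataclass(frozen=True)
class CorrelationNetwork:
    """Thresholded signed correlation network.

    ``edges`` holds (a, b, rho, sign) tuples with |rho| strictly above
    ``threshold``; sign is "positive" or "negative".
    """

    variables: tuple[str, ...]
    rho_matrix: pd.DataFrame
    threshold: float
    edges: tuple[tuple[str, str, float, str], ...]

    def edge_count(self) -> int:
        return len(self.edges)


def spearman_matrix(points: pd.DataFrame, variables: Sequence[str],
                    min_n: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p-values over the chosen variables.

    Missing values are handled pairwise-complete; a pair with fewer than
    ``min_n`` complete observations, or with a constant variable, gets
    rho = NaN (flagged, not raised).  The diagonal is 1 wherever the
    variable is non-constant.
    """
    variables = list(variables)
    data = points[variables].apply(pd.to_numeric, errors="coerce")
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        xi = data.iloc[:, i].to_numpy(dtype=float)
        if np.nanstd(xi[np.isfinite(xi)]) > 0:
            rho[i, i] = 1.0
            pval[i, i] = 0.0
        for j in range(i + 1, k):
            xj = data.iloc[:, j].to_numpy(dtype=float)
            keep = np.isfinite(xi) & np.isfinite(xj)
            if keep.sum() < min_n:
                continue
            a, b = xi[keep], xj[keep]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # constant variable: rho undefined for this pair
            r, p = stats.spearmanr(a, b)
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    idx = pd.Index(variables)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(pval, index=idx, columns=idx))


def build_network(rho_matrix: pd.DataFrame, threshold: float = 0.2) -> CorrelationNetwork:
    """Keep edges with rho strictly above ``threshold`` or below ``-threshold``.

    Self-edges are never produced; NaN correlations never form edges.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    variables = tuple(str(v) for v in rho_matrix.columns)
    edges = []
    for i, a in enumerate(variables):
        for j in range(i + 1, len(variables)):
            b = variables[j]
            r = float(rho_matrix.iloc[i, j])
            if not np.isfinite(r):
                continue
            if r > threshold:
                edges.append((a, b, r, "positive"))
            elif r < -threshold:
                edges.append((a, b, r, "negative"))
    return CorrelationNetwork(variables=variables, rho_matrix=rho_matrix,
                              threshold=float(threshold), edges=tuple(edges))


def to_networkx(network: CorrelationNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.variables)
    for a, b, r, sign in network.edges:
        g.add_edge(a, b, rho=r, sign=sign, weight=abs(r))
    return g


def export_graphml(network: CorrelationNetwork, path: str) -> None:
    nx.write_graphml(to_networkx(network), path)


def edge_table(network: CorrelationNetwork) -> pd.DataFrame:
    return pd.DataFrame(network.edges, columns=["a", "b", "rho", "sign"])


def plot_heatmap(rho_matrix: pd.DataFrame, path: Optional[str] = None):
    """Correlation heatmap (blue–white–red, fixed [-1, 1] scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(rho_matrix) + 2,) * 2)
    im = ax.imshow(rho_matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho_matrix)), rho_matrix.columns, rotation=90)
    ax.set_yticks(range(len(rho_matrix)), rho_matrix.index)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_network(network: CorrelationNetwork, path: Optional[str] = None, seed: int = 0):
    """Spring-layout network with blue positive and red negative edges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = to_networkx(network)
    pos = nx.spring_layout(g, seed=seed)
    colors = ["tab:blue" if g[u][v]["sign"] == "positive" else "tab:red"
              for u, v in g.edges]
    widths = [3 * g[u][v]["weight"] for u, v in g.edges]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(g, pos=pos, ax=ax, edge_color=colors, width=widths,
                     node_color="lightgray", font_size=8)
    ax.set_axis_off()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
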