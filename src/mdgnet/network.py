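"""Thresholded Spearman correlation networks.

Genes are nodes; an undirected edge connects genes A and B whenever the
absolute Spearman rank correlation of their expression profiles across
samples meets the threshold, |SCC(A, B)| >= alpha with alpha in (0, 1].
The only structural parameter used downstream is the average degree 2m/n.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_coefficient",
    "ks_like_round",
    "correlation_matrix",
    "threshold_network",
    "adjacency",
    "degree_vector",
    "average_degree",
]

#: correlations are rounded to this many decimals before threshold
#: comparison so that ties at the threshold are stable across platforms
ROUND_DECIMALS = 12


def spearman_coefficient(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Ties receive average ranks. A constant vector has undefined ranks;
    the coefficient is then reported as 0.0 (with a warning) so that a
    flat profile never creates an edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman coefficient undefined, using 0.0")
        return 0.0
    return float(stats.spearmanr(x, y).statistic)


def ks_like_round(values):
    """Round correlation values for platform-stable threshold ties."""
    return np.round(values, ROUND_DECIMALS)


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman correlation of a genes x samples table.

    Equivalent to the product-moment correlation of row-wise average
    ranks. Rows with zero variance get sentinel correlation 0 to every
    other gene (unit diagonal is kept).
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate genes")
    values = matrix.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.atleast_2d(corr)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0"
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def adjacency(corr: pd.DataFrame, alpha: float) -> np.ndarray:
    """Boolean adjacency |SCC| >= alpha with an empty diagonal."""
    if not 0 < alpha <= 1:
        raise ValueError(f"threshold alpha must be in (0, 1], got {alpha}")
    adj = ks_like_round(np.abs(np.asarray(corr, dtype=float))) >= alpha
    np.fill_diagonal(adj, False)
    return adj


def threshold_network(corr: pd.DataFrame, alpha: float) -> nx.Graph:
    """Build the undirected network at threshold ``alpha``.

    Every gene is a node; edges carry the signed correlation as the
    ``scc`` attribute. The threshold comparison is inclusive (ties at
    exactly alpha are edges).
    """
    if not isinstance(corr, pd.DataFrame):
        corr = pd.DataFrame(np.asarray(corr, dtype=float))
    adj = adjacency(corr, alpha)
    genes = list(corr.index)
    graph = nx.Graph(alpha=alpha)
    graph.add_nodes_from(genes)
    rows, cols = np.nonzero(np.triu(adj, k=1))
    values = corr.to_numpy()
    graph.add_edges_from(
        (genes[i], genes[j], {"scc": float(values[i, j])})
        for i, j in zip(rows, cols)
    )
    return graph


def degree_vector(corr: pd.DataFrame, alpha: float) -> pd.Series:
    """Per-gene degree at threshold ``alpha`` without building a graph."""
    adj = adjacency(corr, alpha)
    index = corr.index if isinstance(corr, pd.DataFrame) else None
    return pd.Series(adj.sum(axis=1), index=index, name=f"degree@{alpha:g}")


def average_degree(net: nx.Graph) -> float:
    """Mean degree 2m/n of a network; 0 for an edgeless graph."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("average degree undefined for an empty node set")
    return 2.0 * net.number_of_edges() / n
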