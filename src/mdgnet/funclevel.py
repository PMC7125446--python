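"""Function-level expression totals and per-gene difference statistics.

The expression level of a biological function F in a cohort is the sum,
over the genes annotated to F, of each gene's mean expression across the
cohort's samples. Comparing totals between control (C) and experimental
(E) cohorts localizes which functions carry the expression difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gene_mean_expression",
    "function_levels",
    "diff_stats",
    "plot_function_levels",
]


def gene_mean_expression(matrix: pd.DataFrame, gene: str) -> float:
    """Arithmetic mean of one gene's expression across samples."""
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    if matrix.shape[1] < 1:
        raise ValueError("matrix has no samples")
    return float(matrix.loc[gene].mean())


def function_levels(
    functions: dict,
    matrix_c: pd.DataFrame,
    matrix_e: pd.DataFrame,
) -> pd.DataFrame:
    """Total expression per function in each cohort.

    ``functions`` maps a function id to its member genes. Each total is
    the sum of member genes' cohort-mean expression; ``difference`` is
    the absolute difference of the two totals.
    """
    rows = []
    for fid, genes in functions.items():
        genes = list(genes)
        for g in genes:
            if g not in matrix_c.index or g not in matrix_e.index:
                raise KeyError(f"function {fid!r} member {g!r} missing from a cohort")
        total_c = float(matrix_c.loc[genes].mean(axis=1).sum())
        total_e = float(matrix_e.loc[genes].mean(axis=1).sum())
        rows.append(
            {
                "function": str(fid),
                "n_genes": len(genes),
                "genes": ",".join(map(str, genes)),
                "total_c": total_c,
                "total_e": total_e,
                "difference": abs(total_c - total_e),
            }
        )
    return pd.DataFrame(rows)


def diff_stats(
    matrix_c: pd.DataFrame,
    matrix_e: pd.DataFrame,
    genes,
    ddof: int = 0,
) -> dict:
    """Summary statistics of per-gene mean-expression differences.

    Over the given genes, computes max/min/mean/variance of
    |mean_C(g) - mean_E(g)|. The variance is the population variance
    (ddof=0) by default.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    diffs = np.array(
        [
            abs(gene_mean_expression(matrix_c, g) - gene_mean_expression(matrix_e, g))
            for g in genes
        ]
    )
    return {
        "max": float(diffs.max()),
        "min": float(diffs.min()),
        "mean": float(diffs.mean()),
        "variance": float(diffs.var(ddof=ddof)),
    }


def plot_function_levels(levels: pd.DataFrame, path=None):
    """Optional grouped bar chart of per-function totals in C and E."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(levels))
    fig, ax = plt.subplots(figsize=(1.2 * len(levels) + 2, 4))
    ax.bar(x - 0.2, levels["total_c"], width=0.4, label="C")
    ax.bar(x + 0.2, levels["total_e"], width=0.4, label="E")
    ax.set_xticks(x, levels["function"])
    ax.set_ylabel("total expression")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
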