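"""Threshold sweeps, cohort separability, and degree-difference ranking.

The two cohorts' correlation networks are compared through their
average-degree curves over a grid of thresholds (default 0.1-0.9). The
cohorts are *separable* when one curve strictly dominates the other at
every grid point; a Monte Carlo null experiment estimates how often two
same-distribution datasets are separable by chance, and its complement
is the confidence attached to an observed separation.

Per-gene degree differences, averaged in absolute value over the grid,
score each gene's structural change between cohorts; the top-k genes are
the maximally-structural-difference genes (MD-Gs, k=20 by default).
The absolute (not relative) difference is used deliberately: relative
change |deg_E - deg_C|/deg_C depends on the reference cohort and blows
up for sparsely connected genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import correlation_matrix, adjacency

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_K",
    "DegreeProfile",
    "SeparabilityResult",
    "MDGRanking",
    "degree_sweep",
    "profile_from_matrices",
    "curve_separability",
    "separability",
    "null_separability_probability",
    "md_scores",
    "top_k",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 1))
DEFAULT_K = 20
NULL_MODELS = ("iid-normal", "label-permutation")


@dataclass
class DegreeProfile:
    """Per-gene degrees and cohort average-degree curves over a grid."""

    thresholds: tuple
    degrees_c: pd.DataFrame  # genes x thresholds
    degrees_e: pd.DataFrame

    @property
    def genes(self):
        return self.degrees_c.index

    @property
    def average_c(self) -> pd.Series:
        return self.degrees_c.mean(axis=0)

    @property
    def average_e(self) -> pd.Series:
        return self.degrees_e.mean(axis=0)

    def average_table(self) -> pd.DataFrame:
        """Cohort average degrees, rows C/E, columns thresholds."""
        return pd.DataFrame(
            [self.average_c, self.average_e], index=["C", "E"]
        )


@dataclass
class SeparabilityResult:
    """Strict-dominance verdict, optionally with Monte Carlo null fields."""

    separable: bool
    direction: str | None = None  # "C" or "E" when separable
    null_probability: float | None = None
    standard_error: float | None = None
    n_replicates: int | None = None
    model: str | None = None
    n_c_dominant: int | None = None
    n_e_dominant: int | None = None

    @property
    def confidence(self) -> float | None:
        if self.null_probability is None:
            return None
        return 1.0 - self.null_probability


@dataclass
class MDGRanking:
    """Genes ranked by mean absolute degree difference across the grid."""

    table: pd.DataFrame = field(repr=False)  # columns: gene_id, score, rank

    def top(self, k: int) -> list[str]:
        return top_k(self, k)


def _degree_table(corr, thresholds) -> pd.DataFrame:
    cols = {}
    for alpha in thresholds:
        cols[alpha] = adjacency(corr, alpha).sum(axis=1)
    return pd.DataFrame(cols, index=corr.index)


def _check_grid(thresholds):
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds:
        raise ValueError("threshold grid must be non-empty")
    if any(not 0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    return thresholds


def degree_sweep(
    matrix_c: pd.DataFrame,
    matrix_e: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> DegreeProfile:
    """Degrees of every gene at every threshold in both cohorts.

    One correlation matrix is computed per cohort and re-thresholded
    across the grid.
    """
    thresholds = _check_grid(thresholds)
    if not matrix_c.index.equals(matrix_e.index):
        raise ValueError("cohort matrices must share identical gene ids in order")
    return profile_from_matrices(
        correlation_matrix(matrix_c), correlation_matrix(matrix_e), thresholds
    )


def profile_from_matrices(corr_c, corr_e, thresholds=DEFAULT_THRESHOLDS) -> DegreeProfile:
    """Degree profile from precomputed cohort correlation matrices."""
    thresholds = _check_grid(thresholds)
    return DegreeProfile(
        thresholds=thresholds,
        degrees_c=_degree_table(corr_c, thresholds),
        degrees_e=_degree_table(corr_e, thresholds),
    )


def curve_separability(curve_c, curve_e) -> SeparabilityResult:
    """Strict dominance of one average-degree curve over the other.

    Any tie at any grid point makes the cohorts non-separable.
    """
    c = np.asarray(curve_c, dtype=float)
    e = np.asarray(curve_e, dtype=float)
    if c.shape != e.shape:
        raise ValueError("curves must share the same threshold grid")
    if np.all(c > e):
        return SeparabilityResult(separable=True, direction="C")
    if np.all(e > c):
        return SeparabilityResult(separable=True, direction="E")
    return SeparabilityResult(separable=False)


def separability(profile: DegreeProfile) -> SeparabilityResult:
    """Separability of the profile's cohort average-degree curves."""
    return curve_separability(
        profile.average_c.to_numpy(), profile.average_e.to_numpy()
    )


def _avg_curves_from_values(xc, xe, thresholds):
    from scipy import stats as _stats

    from .network import ks_like_round

    curves = []
    for x in (xc, xe):
        ranks = _stats.rankdata(x, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(ranks)
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
        np.fill_diagonal(corr, 1.0)
        a = ks_like_round(np.abs(corr))
        curve = np.array(
            [((a >= t).sum(axis=1) - 1).mean() for t in thresholds]
        )
        curves.append(curve)
    return curves


def null_separability_probability(
    n_genes: int,
    n_samples_c: int,
    n_samples_e: int,
    thresholds=DEFAULT_THRESHOLDS,
    n_replicates: int = 200,
    seed: int = 0,
    model: str = "iid-normal",
    data: pd.DataFrame | None = None,
) -> SeparabilityResult:
    """Monte Carlo probability that same-distribution cohorts separate.

    ``model="iid-normal"`` draws both cohorts i.i.d. standard normal at
    the given dimensions. ``model="label-permutation"`` shuffles the
    columns of ``data`` (genes x pooled samples) and splits them into
    pseudo-cohorts of the given sizes, preserving the real correlation
    structure while destroying the cohort labels.

    Returns a :class:`SeparabilityResult` whose ``null_probability`` is
    the fraction of replicate pairs strictly separable in either
    direction, with binomial standard error sqrt(p(1-p)/B) and
    ``confidence = 1 - null_probability``.
    """
    if model not in NULL_MODELS:
        raise ValueError(f"unknown null model {model!r}; expected {NULL_MODELS}")
    if n_replicates < 50:
        raise ValueError("need at least 50 Monte Carlo replicates")
    thresholds = _check_grid(thresholds)
    if model == "label-permutation":
        if data is None:
            raise ValueError("label-permutation model requires the pooled data")
        values = data.to_numpy(dtype=float)
        if values.shape[1] < n_samples_c + n_samples_e:
            raise ValueError("data has fewer samples than the two cohort sizes")

    rng = np.random.default_rng(seed)
    n_sep = n_c = n_e = 0
    for _ in range(n_replicates):
        if model == "iid-normal":
            xc = rng.standard_normal((n_genes, n_samples_c))
            xe = rng.standard_normal((n_genes, n_samples_e))
        else:
            perm = rng.permutation(values.shape[1])
            xc = values[:, perm[:n_samples_c]]
            xe = values[:, perm[n_samples_c : n_samples_c + n_samples_e]]
        curve_c, curve_e = _avg_curves_from_values(xc, xe, thresholds)
        verdict = curve_separability(curve_c, curve_e)
        if verdict.separable:
            n_sep += 1
            if verdict.direction == "C":
                n_c += 1
            else:
                n_e += 1
    estimate = n_sep / n_replicates
    return SeparabilityResult(
        separable=bool(n_sep),
        direction=None,
        null_probability=estimate,
        standard_error=float(np.sqrt(estimate * (1 - estimate) / n_replicates)),
        n_replicates=n_replicates,
        model=model,
        n_c_dominant=n_c,
        n_e_dominant=n_e,
    )


def md_scores(profile: DegreeProfile) -> MDGRanking:
    """Score every gene by its mean absolute degree difference.

    score(g) = mean over the grid of |deg_C(g, alpha) - deg_E(g, alpha)|.
    Genes are ranked by descending score; equal scores break ties by
    ascending gene id so the ranking is deterministic.
    """
    diff = (profile.degrees_c - profile.degrees_e).abs()
    scores = diff.mean(axis=1)
    table = pd.DataFrame(
        {"gene_id": scores.index.astype(str), "score": scores.to_numpy(dtype=float)}
    )
    table = table.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return MDGRanking(table=table)


def top_k(ranking: MDGRanking, k: int) -> list[str]:
    """First k gene ids by descending score (ties by ascending id)."""
    n = len(ranking.table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return ranking.table["gene_id"].head(k).to_list()
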