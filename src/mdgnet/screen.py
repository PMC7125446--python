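"""Per-gene hypothesis-test cascade for cohort-differential expression.

For each gene the two cohorts' expression vectors are compared with a
decision tree:

1. two-sample Kolmogorov-Smirnov test — a distribution-shape difference
   exits immediately as differential (route ``KS2-different``);
2. one-sample KS normality check on each cohort (standardized values);
3. if both cohorts look normal, an F test for variance homogeneity
   chooses between the pooled t test and Welch's t test;
4. otherwise the Mann-Whitney rank test compares locations.

Each stage has its own Benjamini-Hochberg FDR cutoff; the defaults
(0.0005, 0.001, 0.001, 0.001) are deliberately strict so that only
clearly differential genes survive. A gene is flagged when it exits at
stage 1 or when its final location-test q-value passes the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CascadeCutoffs",
    "ROUTES",
    "two_sample_ks",
    "ks_statistic",
    "normality_ks",
    "variance_f_test",
    "location_test",
    "mannwhitney_exact_p",
    "bh_adjust",
    "screen_genes",
    "flagged_genes",
]

ROUTES = ("KS2-different", "t", "Welch", "MannWhitney")

#: route columns in the screen table, in cascade order
SCREEN_COLUMNS = [
    "gene_id", "route",
    "p_ks2", "q_ks2",
    "p_norm_c", "q_norm_c", "p_norm_e", "q_norm_e",
    "p_f", "q_f",
    "p_loc", "q_loc",
    "flagged",
]


class DegenerateSampleError(ValueError):
    """A sample violates a test's preconditions (e.g. zero variance)."""


@dataclass(frozen=True)
class CascadeCutoffs:
    """FDR cutoffs for the four cascade stages."""

    q_ks2: float = 0.0005
    q_ksnorm: float = 0.001
    q_f: float = 0.001
    q_loc: float = 0.001

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not 0 < value < 1:
                raise ValueError(f"cutoff {name} must be in (0, 1), got {value}")


def _as_sample(x, minimum=2):
    x = np.asarray(x, dtype=float).ravel()
    if x.size < minimum:
        raise ValueError(f"sample must contain at least {minimum} values")
    return x


def ks_statistic(x, y) -> float:
    """Sup-distance between the two samples' empirical CDFs."""
    x, y = _as_sample(x), _as_sample(y)
    return float(stats.ks_2samp(x, y).statistic)


def two_sample_ks(x, y) -> float:
    """Two-sample KS p-value (exact for small samples, else asymptotic)."""
    x, y = _as_sample(x), _as_sample(y)
    return float(stats.ks_2samp(x, y).pvalue)


def normality_ks(x, lilliefors: bool = False) -> float:
    """One-sample KS normality p-value on standardized values.

    Values are centred and scaled by the sample mean and SD before
    comparison with N(0, 1). With estimated parameters the classical KS
    p-value is conservative (it over-states normality); passing
    ``lilliefors=True`` applies the Lilliefors correction instead.
    A constant sample returns 0.0 (decisively non-normal).
    """
    x = _as_sample(x, minimum=3)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    z = (x - x.mean()) / sd
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    return float(stats.kstest(z, "norm").pvalue)


def variance_f_test(x, y) -> float:
    """Two-sided variance-ratio F test.

    p = 2 * min(P(F <= f), P(F >= f)) capped at 1, with F = s_x^2/s_y^2
    on (n_x - 1, n_y - 1) degrees of freedom; symmetric in its arguments.
    """
    x, y = _as_sample(x), _as_sample(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateSampleError("zero variance: F test undefined")
    f = vx / vy
    dist = stats.f(x.size - 1, y.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def mannwhitney_exact_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments.

    Intended for small samples (combined size <= ~16); used as the exact
    route of :func:`location_test` and as an independent enumeration
    check. Requires distinct values across the combined sample.
    """
    x, y = _as_sample(x), _as_sample(y)
    combined = np.concatenate([x, y])
    if np.unique(combined).size != combined.size:
        raise ValueError("exact enumeration requires all values distinct")
    n, m = x.size, y.size
    ranks = stats.rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    # null distribution of U: every n-subset of the pooled ranks equally likely
    pooled = np.arange(1.0, n + m + 1)
    stat = min(u_obs, n * m - u_obs)
    count = total = 0
    for subset in combinations(pooled, n):
        u = sum(subset) - n * (n + 1) / 2
        total += 1
        if min(u, n * m - u) <= stat + 1e-12:
            count += 1
    return count / total


def location_test(x, y, route: str) -> float:
    """Two-sided location-difference p-value for one cascade route.

    ``t`` uses the pooled-variance t test, ``Welch`` the Satterthwaite
    approximation, ``MannWhitney`` rank sums (exact enumeration when both
    samples have <= 8 untied values, otherwise the normal approximation
    with continuity and tie correction). Completely tied data returns 1.
    """
    x, y = _as_sample(x), _as_sample(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if route == "t":
        return float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    if route == "Welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    if route == "MannWhitney":
        combined = np.concatenate([x, y])
        small = max(x.size, y.size) <= 8
        no_ties = np.unique(combined).size == combined.size
        if small and no_ties:
            return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
        return float(
            stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
        )
    raise ValueError(f"unknown location route {route!r}; expected t/Welch/MannWhitney")


def bh_adjust(p_values, total_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    ``total_tests`` widens the family beyond the supplied p-values (used
    by the cascade's "global" FDR scope, where every stage is corrected
    as if all genes had been tested at that stage).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if total_tests is None:
        return multipletests(p, method="fdr_bh")[1]
    if total_tests < p.size:
        raise ValueError("total_tests cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * total_tests / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _stage_family(n_tested, n_total, scope):
    return n_total if scope == "global" else None


def screen_genes(
    matrix_c: pd.DataFrame,
    matrix_e: pd.DataFrame,
    cutoffs: CascadeCutoffs = CascadeCutoffs(),
    fdr_scope: str = "staged",
    normality_rule: str = "both",
    lilliefors: bool = False,
) -> pd.DataFrame:
    """Run the full test cascade over aligned cohort matrices.

    Parameters
    ----------
    matrix_c, matrix_e
        genes x samples tables sharing the same gene index (same order).
    cutoffs
        per-stage FDR cutoffs.
    fdr_scope
        ``"staged"`` (default): each stage's BH family is the genes that
        reach that stage. ``"global"``: every stage is adjusted as if all
        genes had been tested (family size = total gene count).
    normality_rule
        ``"both"`` (default): a gene is treated as normal only when both
        cohorts pass the normality cutoff. ``"fisher"``: the two cohorts'
        KS p-values are combined with Fisher's method into a single test.
    lilliefors
        use the Lilliefors-corrected normality p-values.

    Returns
    -------
    DataFrame with one row per gene (``SCREEN_COLUMNS``); stages a gene
    never reached are NaN. ``flagged`` is True iff the gene exited with
    route ``KS2-different`` or its location q-value passed ``q_loc``.
    """
    if fdr_scope not in ("staged", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    if normality_rule not in ("both", "fisher"):
        raise ValueError(f"unknown normality_rule {normality_rule!r}")
    if not matrix_c.index.equals(matrix_e.index):
        raise ValueError("cohort matrices must share identical gene ids in order")
    if matrix_c.shape[1] < 2 or matrix_e.shape[1] < 2:
        raise ValueError("each cohort needs at least 2 samples")

    genes = matrix_c.index.to_list()
    n = len(genes)
    xc = matrix_c.to_numpy(dtype=float)
    xe = matrix_e.to_numpy(dtype=float)

    out = pd.DataFrame(index=range(n), columns=SCREEN_COLUMNS)
    out["gene_id"] = genes

    # stage 1: two-sample KS across all genes
    p_ks2 = np.array([two_sample_ks(xc[i], xe[i]) for i in range(n)])
    q_ks2 = bh_adjust(p_ks2, _stage_family(n, n, fdr_scope))
    out["p_ks2"], out["q_ks2"] = p_ks2, q_ks2
    shape_diff = q_ks2 <= cutoffs.q_ks2
    out.loc[shape_diff, "route"] = "KS2-different"

    remaining = np.flatnonzero(~shape_diff)

    # degenerate genes (zero variance in a cohort) skip the parametric
    # stages entirely and fall through to Mann-Whitney
    degenerate = np.array(
        [xc[i].std(ddof=1) == 0 or xe[i].std(ddof=1) == 0 for i in remaining]
    )
    testable = remaining[~degenerate]

    # stage 2: normality per cohort, each cohort its own BH family
    normal = np.zeros(n, dtype=bool)
    if testable.size:
        p_nc = np.array([normality_ks(xc[i], lilliefors) for i in testable])
        p_ne = np.array([normality_ks(xe[i], lilliefors) for i in testable])
        fam = _stage_family(testable.size, n, fdr_scope)
        if normality_rule == "fisher":
            p_comb = np.array(
                [stats.combine_pvalues([a, b]).pvalue for a, b in zip(p_nc, p_ne)]
            )
            q_comb = bh_adjust(p_comb, fam)
            q_nc = q_ne = q_comb
            normal[testable] = q_comb > cutoffs.q_ksnorm
        else:
            q_nc = bh_adjust(p_nc, fam)
            q_ne = bh_adjust(p_ne, fam)
            normal[testable] = (q_nc > cutoffs.q_ksnorm) & (q_ne > cutoffs.q_ksnorm)
        out.loc[testable, "p_norm_c"], out.loc[testable, "q_norm_c"] = p_nc, q_nc
        out.loc[testable, "p_norm_e"], out.loc[testable, "q_norm_e"] = p_ne, q_ne

    # stage 3: F test on the both-normal stratum
    f_stratum = np.flatnonzero(normal)
    if f_stratum.size:
        p_f = np.array([variance_f_test(xc[i], xe[i]) for i in f_stratum])
        q_f = bh_adjust(p_f, _stage_family(f_stratum.size, n, fdr_scope))
        out.loc[f_stratum, "p_f"], out.loc[f_stratum, "q_f"] = p_f, q_f
        homogeneous = q_f > cutoffs.q_f
        out.loc[f_stratum[homogeneous], "route"] = "t"
        out.loc[f_stratum[~homogeneous], "route"] = "Welch"

    mw = np.setdiff1d(remaining, f_stratum)
    out.loc[mw, "route"] = "MannWhitney"

    # stage 4: location tests, one BH family across every gene reaching one
    if remaining.size:
        p_loc = np.array(
            [location_test(xc[i], xe[i], out.at[i, "route"]) for i in remaining]
        )
        q_loc = bh_adjust(p_loc, _stage_family(remaining.size, n, fdr_scope))
        out.loc[remaining, "p_loc"], out.loc[remaining, "q_loc"] = p_loc, q_loc

    out["flagged"] = shape_diff | (
        out["q_loc"].to_numpy(dtype=float) <= cutoffs.q_loc
    )
    for col in SCREEN_COLUMNS[2:-1]:
        out[col] = out[col].astype(float)
    out["flagged"] = out["flagged"].astype(bool)
    return out


def flagged_genes(records: pd.DataFrame) -> list[str]:
    """Gene ids flagged as cohort-differential, in input order."""
    return records.loc[records["flagged"], "gene_id"].to_list()
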