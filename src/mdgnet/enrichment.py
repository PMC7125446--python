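"""Hypergeometric gene-set enrichment with kappa-similarity clustering.

A self-contained reimplementation of the DAVID/Metascape-style workflow
against user-supplied GMT gene sets: upper-tail hypergeometric p-values,
Benjamini-Hochberg q-values across all tested terms, the standard
(p < 0.01, count >= 3, enrichment factor > 1.5) retention filters,
Cohen's-kappa term similarity over the query list, average-linkage
hierarchical clustering with a 0.3 similarity cut, and a smallest-p
representative per cluster. No ontology databases are bundled; callers
provide their own annotation in GMT form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .screen import bh_adjust

__all__ = [
    "GeneSetCollection",
    "EnrichmentCluster",
    "hypergeom_upper_tail",
    "enrich",
    "kappa_similarity",
    "cluster_terms",
]

ENRICH_COLUMNS = [
    "term", "description", "k", "K", "n", "N",
    "p", "q", "factor", "genes", "retained",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the background universe.

    By default the universe is the union of all term genes — "all genes
    in the genome" is not reproducible without fixing an annotation
    release, so the annotation itself defines the background. Pass an
    explicit ``universe`` to override.
    """

    sets: dict
    descriptions: dict = field(default_factory=dict)
    universe: frozenset = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.sets:
            raise ValueError("collection must contain at least one term")
        clean = {str(t): frozenset(map(str, g)) for t, g in self.sets.items()}
        if any(len(g) == 0 for g in clean.values()):
            raise ValueError("empty terms are not allowed")
        object.__setattr__(self, "sets", clean)
        if self.universe is None:
            object.__setattr__(
                self, "universe", frozenset().union(*clean.values())
            )
        else:
            universe = frozenset(map(str, self.universe))
            for term, genes in clean.items():
                if not genes <= universe:
                    raise ValueError(f"term {term!r} is not contained in the universe")
            object.__setattr__(self, "universe", universe)

    def __len__(self):
        return len(self.sets)


@dataclass
class EnrichmentCluster:
    """A group of kappa-similar enriched terms with its representative."""

    members: list
    representative: str
    kappa: pd.DataFrame = field(repr=False)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = term size, n = query size, k = overlap.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    collection: GeneSetCollection,
    p_max: float = 0.01,
    min_count: int = 3,
    min_factor: float = 1.5,
) -> pd.DataFrame:
    """Test every term of the collection against a query gene list.

    The query is intersected with the universe first. q-values are BH
    adjusted across *all* tested terms (the full multiple-testing
    family), then the ``retained`` column marks terms passing all three
    filters: p < p_max, overlap count >= min_count and enrichment factor
    k/(K*n/N) > min_factor. Rows are sorted by ascending p (ties by
    term id).
    """
    query = frozenset(map(str, query))
    effective = query & collection.universe
    if not effective:
        raise ValueError("query does not intersect the collection universe")
    N = len(collection.universe)
    n = len(effective)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        overlap = sorted(effective & members)
        K, k = len(members), len(overlap)
        expected = K * n / N
        rows.append(
            {
                "term": term,
                "description": collection.descriptions.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(N, K, n, k),
                "factor": k / expected if expected > 0 else 0.0,
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["retained"] = (
        (table["p"] < p_max)
        & (table["k"] >= min_count)
        & (table["factor"] > min_factor)
    )
    table = table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return table[ENRICH_COLUMNS]


def kappa_similarity(term_a, term_b, query) -> float:
    """Cohen's kappa of two terms' membership indicators over the query.

    Chance-corrected agreement of the binary vectors "gene in term A" /
    "gene in term B" restricted to the query genes. When the expected
    agreement is 1 (both indicators constant) kappa is defined as 1 if
    the observed agreement is also 1, else 0.
    """
    query = [str(g) for g in dict.fromkeys(query)]
    if not query:
        raise ValueError("query must be non-empty")
    a = np.array([g in term_a for g in query])
    b = np.array([g in term_b for g in query])
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def _kappa_matrix(terms, collection, query) -> pd.DataFrame:
    k = len(terms)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = kappa_similarity(
                collection.sets[terms[i]], collection.sets[terms[j]], query
            )
    return pd.DataFrame(mat, index=terms, columns=terms)


def cluster_terms(
    table: pd.DataFrame,
    collection: GeneSetCollection,
    query,
    similarity_cut: float = 0.3,
    method: str = "average",
) -> list[EnrichmentCluster]:
    """Group retained terms into kappa-similarity clusters.

    Hierarchical clustering (default average linkage) on distance
    1 - kappa; maximal subtrees whose merges all have similarity
    strictly above ``similarity_cut`` form clusters (singletons
    allowed). Each cluster is represented by its smallest-p member,
    ties broken by the lexicographically smaller term id. Input order
    does not matter: terms are canonically ordered by (p, term) first.
    """
    retained = table.loc[table["retained"]] if "retained" in table else table
    if retained.empty:
        raise ValueError("no retained terms to cluster")
    ordered = retained.sort_values(["p", "term"], kind="stable")
    terms = ordered["term"].to_list()
    query = [str(g) for g in dict.fromkeys(query)]
    kappa = _kappa_matrix(terms, collection, query)
    if len(terms) == 1:
        labels = np.array([1])
    else:
        distance = 1.0 - kappa.to_numpy()
        np.fill_diagonal(distance, 0.0)
        z = linkage(squareform(distance, checks=False), method=method)
        # merge allowed while similarity > cut, i.e. distance < 1 - cut
        labels = fcluster(z, t=(1.0 - similarity_cut) - 1e-9, criterion="distance")
    clusters = []
    for label in sorted(set(labels)):
        members = [t for t, l in zip(terms, labels) if l == label]
        # ordered by (p, term) already, so the first member represents
        clusters.append(
            EnrichmentCluster(
                members=members,
                representative=members[0],
                kappa=kappa.loc[members, members],
            )
        )
    clusters.sort(key=lambda c: terms.index(c.representative))
    return clusters
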