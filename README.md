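# mdgnet

Differential co-expression **network-structure** analysis for two-cohort
gene-expression studies (control cohort *C* vs experimental cohort *E*).
Instead of asking only which genes change their expression level, `mdgnet`
asks which genes change their *connectivity*: it builds thresholded Spearman
correlation networks per cohort, compares their average degrees across a
grid of thresholds, and ranks genes by how much their degree differs between
cohorts. It is aimed at researchers analyzing case/control transcriptomics
(e.g. peripheral-blood microarray cohorts) who want a transparent,
fully scriptable alternative to web-service pipelines.

## What it computes

1. **Screening cascade** (`mdgnet.screen`). Each gene is tested per cohort
   pair through a decision tree: two-sample Kolmogorov–Smirnov
   (distribution shape) → one-sample KS normality per cohort → F test for
   variance homogeneity → pooled *t* / Welch *t* / Mann–Whitney. Each stage
   is Benjamini–Hochberg adjusted with its own FDR cutoff
   (defaults 0.0005, 0.001, 0.001, 0.001). A gene is *flagged* when its
   distributions differ in shape or its final location q-value passes.
2. **Correlation networks** (`mdgnet.network`). For genes *A*, *B*, an edge
   exists at threshold α ∈ (0, 1] iff |SCC(*A*, *B*)| ≥ α, where SCC is the
   Spearman rank correlation across samples. The structural parameter is
   the average degree 2m/n.
3. **Degree analysis** (`mdgnet.degree`). Degrees are swept over
   α ∈ {0.1, …, 0.9}. The cohorts are *separable* when one average-degree
   curve strictly dominates the other at every threshold; a Monte Carlo
   null experiment (i.i.d.-normal or label-permutation model) estimates how
   often that happens by chance, and 1 − that probability is the confidence
   in an observed separation. Each gene is scored by
   score(g) = mean over α of |deg_C(g, α) − deg_E(g, α)|,
   and the top-k genes (k = 20) are the **maximally structural difference
   genes (MD-Gs)**.
4. **Enrichment** (`mdgnet.enrichment`). Upper-tail hypergeometric tests of
   the MD-G list against user-supplied GMT gene sets, BH q-values, the
   standard retention filters (p < 0.01, count ≥ 3, enrichment factor
   k/(K·n/N) > 1.5), Cohen's-kappa term similarity over the query, and
   average-linkage clustering with a 0.3 similarity cut; each cluster is
   represented by its smallest-p term.
5. **Function-level expression** (`mdgnet.funclevel`). Per-function totals
   (sum of member genes' cohort-mean expression) and per-gene
   mean-difference statistics.
6. **Synthetic data** (`mdgnet.simulate`). Seeded generators that plant
   distribution differences for every cascade branch and connectivity
   changes (factor modules with cohort-specific loadings) with recorded
   ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from mdgnet import simulate, degree, screen

# plant a 30-gene module whose first 5 genes are tightly co-expressed in C
# (loading 0.9) but decoupled in E (loading 0.1), over 200 background genes
config = simulate.SimConfig(
    n_genes=230, n_samples_c=60, n_samples_e=60, seed=7,
    de_block_sizes=(0, 0, 0, 0, 230),
    module_spec=((30, 0.9, 0.1, 5),),
)
ds = simulate.gen_connectivity_dataset(config)

profile = degree.degree_sweep(ds.matrix_c, ds.matrix_e)
print(profile.average_table().round(2).iloc[:, :4])
ranking = degree.md_scores(profile)
print(degree.top_k(ranking, 5), "| planted:", sorted(ds.truth_mdg))
```

Output:

```
      0.1    0.2   0.3   0.4
C  105.77  32.86  7.97  4.10
E  105.51  32.49  7.20  2.99
['g0002', 'g0001', 'g0003', 'g0004', 'g0005'] | planted: ['g0001', 'g0002', 'g0003', 'g0004', 'g0005']
```

The average-degree rows show each cohort's mean connectivity at the first
four thresholds, and the five planted loading-drop genes are recovered as
the top five MD-Gs: their degree collapses in E while the background is
symmetric between cohorts.

The same stages run from the shell via the `mdgnet` CLI
(`simulate`, `screen`, `network`, `mdg`, `enrich`, `funclevel`, and `run`
for a full YAML-configured pipeline).

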