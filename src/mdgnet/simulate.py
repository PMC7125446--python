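"""Synthetic cohort expression data with known ground truth.

The generators emulate a two-cohort microarray design — a control cohort
C of 64 samples and an experimental cohort E of 82 samples over a few
hundred to a few thousand genes — so that every downstream stage of the
pipeline can be exercised and validated without any external download.

Two kinds of signal can be planted:

* *distribution differences* (:func:`gen_de_dataset`): blocks of genes
  whose C/E distributions differ in shape, mean, or variance, designed
  to exit through each branch of the screening cascade;
* *connectivity differences* (:func:`gen_connectivity_dataset`): factor
  modules x_g = lambda_g * f + sqrt(1 - lambda_g^2) * eps in which a few
  "planted" genes are strongly loaded on the shared factor in C but
  nearly unloaded in E, so their network degree collapses between
  cohorts while their marginal distribution stays standard normal.

All randomness flows from a single integer seed through one named
generator per dataset, so identical configurations reproduce identical
data byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BRANCHES",
    "ModuleSpec",
    "SimConfig",
    "LabeledDataset",
    "gen_null_pair",
    "gen_de_dataset",
    "gen_connectivity_dataset",
    "gen_gene_sets",
]

#: cascade branches a dataset can plant, in block order
BRANCHES = ("shape", "mean-shift", "variance-shift", "nonnormal-shift", "null")

# branch (a): "contaminated" two-normal mixture with mean 0 and variance 1.
# A narrow spike holds 97% of the mass slightly left of zero and a broad
# component at +5 balances the moments; the sup-CDF distance to N(0,1) is
# ~0.5, which the two-sample KS detects decisively at n ~ 60-80 while the
# matched mean/variance keep the location and scale tests blind to it.
_SHAPE_W = 0.97
_SHAPE_SPIKE_SD = 0.02
_SHAPE_BROAD_MEAN = 5.0
_SHAPE_SPIKE_MEAN = -(1 - _SHAPE_W) * _SHAPE_BROAD_MEAN / _SHAPE_W
_SHAPE_BROAD_SD = float(
    np.sqrt(
        (
            1.0
            - _SHAPE_W * (_SHAPE_SPIKE_MEAN**2 + _SHAPE_SPIKE_SD**2)
            - (1 - _SHAPE_W) * _SHAPE_BROAD_MEAN**2
        )
        / (1 - _SHAPE_W)
    )
)

# branch (d): sharply bimodal two-normal mixture at +-1 (component sd
# 0.05), standardized to unit variance; the same shape in both cohorts so
# the two-sample KS stays silent at zero shift, while the one-sample
# normality KS rejects it decisively at cohort sizes ~ 60-80.
_BIMODAL_MODE = 1.0
_BIMODAL_SD = 0.05
_BIMODAL_SCALE = float(np.sqrt(_BIMODAL_MODE**2 + _BIMODAL_SD**2))

#: variance ratio for the unequal-variance (Welch) branch
VARIANCE_FACTOR = 4.0


@dataclass(frozen=True)
class ModuleSpec:
    """One co-expression module: size, loadings, number of planted genes."""

    size: int
    rho_c: float
    rho_e: float
    n_planted: int

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("module size must be positive")
        if not (0 <= self.rho_c < 1 and 0 <= self.rho_e < 1):
            raise ValueError("module loadings must lie in [0, 1)")
        if not 0 <= self.n_planted <= self.size:
            raise ValueError("n_planted must be between 0 and the module size")
        if self.n_planted > 0 and not self.rho_e < self.rho_c:
            raise ValueError("planted modules require rho_e < rho_c")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic two-cohort dataset.

    ``de_block_sizes`` gives the gene counts per cascade branch in the
    order of :data:`BRANCHES`; any genes left over beyond the blocks are
    additional nulls. ``effect_size`` is the standardized location shift
    delta applied by the mean-shift branches. ``module_spec`` lists the
    co-expression modules for connectivity datasets.
    """

    n_genes: int = 500
    n_samples_c: int = 64
    n_samples_e: int = 82
    seed: int = 0
    de_block_sizes: tuple = (50, 50, 50, 50, 300)
    effect_size: float = 3.0
    module_spec: tuple = ()

    def __post_init__(self):
        if min(self.n_genes, self.n_samples_c, self.n_samples_e) < 2:
            raise ValueError("gene and sample counts must be at least 2")
        blocks = tuple(int(b) for b in self.de_block_sizes)
        if len(blocks) != len(BRANCHES) or any(b < 0 for b in blocks):
            raise ValueError(
                f"de_block_sizes needs {len(BRANCHES)} non-negative counts"
            )
        if sum(blocks) > self.n_genes:
            raise ValueError("de_block_sizes sum exceeds n_genes")
        object.__setattr__(self, "de_block_sizes", blocks)
        modules = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m)
            for m in self.module_spec
        )
        if sum(m.size for m in modules) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        object.__setattr__(self, "module_spec", modules)


@dataclass
class LabeledDataset:
    """Synthetic cohort pair with per-gene ground-truth labels."""

    matrix_c: pd.DataFrame
    matrix_e: pd.DataFrame
    truth_de: pd.Series = field(default=None, repr=False)
    truth_mdg: frozenset = frozenset()

    def __post_init__(self):
        if not self.matrix_c.index.equals(self.matrix_e.index):
            raise ValueError("cohort matrices must share gene ids in order")
        if not self.truth_mdg <= set(self.matrix_c.index):
            raise ValueError("truth_mdg must be a subset of the gene ids")

    def write(self, outdir):
        """Write cohort tables and truth labels as tab-delimited text."""
        from . import io as _io
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_expression(self.matrix_c, outdir / "expression_C.tsv")
        _io.write_expression(self.matrix_e, outdir / "expression_E.tsv")
        truth = pd.DataFrame({"gene_id": self.matrix_c.index.astype(str)})
        truth["branch"] = (
            self.truth_de.reindex(self.matrix_c.index).astype(str).to_numpy()
            if self.truth_de is not None
            else ""
        )
        truth["planted_mdg"] = [
            int(g in self.truth_mdg) for g in self.matrix_c.index
        ]
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _gene_ids(n: int) -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"g{i + 1:0{width}d}" for i in range(n)], name="gene_id")


def _frame(values, genes, prefix):
    return pd.DataFrame(
        values, index=genes,
        columns=[f"{prefix}{j + 1:03d}" for j in range(values.shape[1])],
    )


def gen_null_pair(n_genes, n_samples_c, n_samples_e, seed):
    """Two cohorts of i.i.d. standard-normal expression (no signal)."""
    if min(n_genes, n_samples_c, n_samples_e) < 2:
        raise ValueError("dimensions must be at least 2")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    mc = _frame(rng.standard_normal((n_genes, n_samples_c)), genes, "C")
    me = _frame(rng.standard_normal((n_genes, n_samples_e)), genes, "E")
    return mc, me


def _shape_mixture(rng, size):
    spike = rng.random(size) < _SHAPE_W
    return np.where(
        spike,
        rng.normal(_SHAPE_SPIKE_MEAN, _SHAPE_SPIKE_SD, size),
        rng.normal(_SHAPE_BROAD_MEAN, _SHAPE_BROAD_SD, size),
    )


def _bimodal(rng, size, shift=0.0):
    sign = np.where(rng.random(size) < 0.5, -_BIMODAL_MODE, _BIMODAL_MODE)
    return rng.normal(sign, _BIMODAL_SD, size) / _BIMODAL_SCALE + shift


def gen_de_dataset(config: SimConfig) -> LabeledDataset:
    """Cohort pair with blocks of genes exercising each cascade branch.

    Per branch, with delta = ``config.effect_size``:

    * ``shape``: C standard normal, E the matched-moment contaminated
      mixture (two-sample-KS exit; independent of delta);
    * ``mean-shift``: both normal, E mean delta, equal variance (t);
    * ``variance-shift``: both normal, E mean delta and variance
      ``VARIANCE_FACTOR`` (Welch);
    * ``nonnormal-shift``: both sharply bimodal with the same shape,
      E shifted by delta (Mann-Whitney);
    * ``null``: identical standard normals.
    """
    rng = np.random.default_rng(config.seed)
    n, sc, se = config.n_genes, config.n_samples_c, config.n_samples_e
    delta = config.effect_size
    genes = _gene_ids(n)

    xc = rng.standard_normal((n, sc))
    xe = np.empty((n, se))
    labels = np.full(n, "null", dtype=object)
    start = 0
    blocks = dict(zip(BRANCHES, config.de_block_sizes))
    for branch in BRANCHES:
        size = blocks[branch]
        rows = slice(start, start + size)
        shape = (size, se)
        if branch == "shape":
            xe[rows] = _shape_mixture(rng, shape)
        elif branch == "mean-shift":
            xe[rows] = rng.normal(delta, 1.0, shape)
        elif branch == "variance-shift":
            xe[rows] = rng.normal(delta, np.sqrt(VARIANCE_FACTOR), shape)
        elif branch == "nonnormal-shift":
            xc[rows] = _bimodal(rng, (size, sc))
            xe[rows] = _bimodal(rng, shape, shift=delta)
        else:
            xe[rows] = rng.standard_normal(shape)
        labels[rows] = branch
        start += size
    xe[start:] = rng.standard_normal((n - start, se))

    return LabeledDataset(
        matrix_c=_frame(xc, genes, "C"),
        matrix_e=_frame(xe, genes, "E"),
        truth_de=pd.Series(labels, index=genes, name="branch"),
        truth_mdg=frozenset(),
    )


def gen_connectivity_dataset(config: SimConfig) -> LabeledDataset:
    """Cohort pair with factor modules and planted connectivity changes.

    Module genes follow x_g = lambda_g * f + sqrt(1 - lambda_g^2) * eps
    with one shared factor f per sample and cohort; planted genes load
    rho_c in C but rho_e in E, the remaining module genes load rho_c in
    both cohorts, and genes outside every module are independent noise.
    Every gene is marginally standard normal, so connectivity is the
    only planted difference.
    """
    if not config.module_spec:
        raise ValueError("connectivity dataset requires at least one module")
    rng = np.random.default_rng(config.seed)
    n, sc, se = config.n_genes, config.n_samples_c, config.n_samples_e
    genes = _gene_ids(n)

    xc = rng.standard_normal((n, sc))
    xe = rng.standard_normal((n, se))
    planted = []
    start = 0
    for module in config.module_spec:
        fc = rng.standard_normal(sc)
        fe = rng.standard_normal(se)
        for j in range(module.size):
            i = start + j
            lam_c = module.rho_c
            lam_e = module.rho_e if j < module.n_planted else module.rho_c
            xc[i] = lam_c * fc + np.sqrt(1 - lam_c**2) * xc[i]
            xe[i] = lam_e * fe + np.sqrt(1 - lam_e**2) * xe[i]
            if j < module.n_planted:
                planted.append(genes[i])
        start += module.size

    return LabeledDataset(
        matrix_c=_frame(xc, genes, "C"),
        matrix_e=_frame(xe, genes, "E"),
        truth_de=pd.Series("null", index=genes, name="branch"),
        truth_mdg=frozenset(planted),
    )


def gen_gene_sets(
    gene_ids,
    n_terms: int,
    term_size_range=(5, 25),
    planted_term_genes=None,
    seed: int = 0,
):
    """Random GMT-style gene sets over a gene universe.

    Draws ``n_terms`` terms with sizes uniform in ``term_size_range``.
    When ``planted_term_genes`` is given, the first term (``T001``)
    contains all of those genes (padded with random genes up to a size
    in range), making it deliberately enriched for any query that
    includes them. Term members are stored sorted, so writing the
    collection to GMT is byte-reproducible.
    """
    from .enrichment import GeneSetCollection

    gene_ids = [str(g) for g in gene_ids]
    if not gene_ids:
        raise ValueError("gene universe must be non-empty")
    lo, hi = int(term_size_range[0]), int(term_size_range[1])
    if not 1 <= lo <= hi <= len(gene_ids):
        raise ValueError("term sizes must fit inside the gene universe")
    planted = [str(g) for g in (planted_term_genes or [])]
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes not in the universe: {sorted(unknown)}")
    if len(planted) > hi:
        raise ValueError("planted_term_genes exceed the maximum term size")

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_terms)))
    sets, descriptions = {}, {}
    for t in range(n_terms):
        name = f"T{t + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if t == 0 and planted:
            size = max(size, len(planted))
            pool = [g for g in gene_ids if g not in planted]
            fill = rng.choice(pool, size=size - len(planted), replace=False)
            members = sorted(set(planted) | set(fill))
            descriptions[name] = "synthetic planted term"
        else:
            members = sorted(rng.choice(gene_ids, size=size, replace=False))
            descriptions[name] = "synthetic term"
        sets[name] = frozenset(members)
    return GeneSetCollection(
        sets=sets, descriptions=descriptions, universe=frozenset(gene_ids)
    )
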