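"""End-to-end orchestration: screen -> networks -> MD-Gs -> enrichment.

:func:`run_pipeline` chains the stages with the study defaults (cascade
cutoffs 0.0005/0.001/0.001/0.001, threshold grid 0.1-0.9, top-20 MD-Gs,
enrichment filters p<0.01 / count>=3 / factor>1.5 with kappa cut 0.3)
and writes every intermediate table so stages remain independently
scriptable. All randomness is controlled by the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as _pd
import yaml

from . import degree, enrichment, funclevel, io, screen

log = logging.getLogger("mdgnet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, parameters and output location for a full run."""

    # inputs: either expression+groups, or expression_c+expression_e
    expression: str | None = None
    groups: str | None = None
    expression_c: str | None = None
    expression_e: str | None = None
    gmt: str | None = None
    out_dir: str = "mdgnet_out"

    # screening
    q_ks2: float = 0.0005
    q_ksnorm: float = 0.001
    q_f: float = 0.001
    q_loc: float = 0.001
    fdr_scope: str = "staged"
    normality_rule: str = "both"
    lilliefors: bool = False

    # networks / MD-Gs
    thresholds: tuple = degree.DEFAULT_THRESHOLDS
    k: int = degree.DEFAULT_K

    # null experiment
    null_model: str = "iid-normal"
    null_replicates: int = 200
    seed: int = 0

    # enrichment
    p_max: float = 0.01
    min_count: int = 3
    min_factor: float = 1.5
    similarity_cut: float = 0.3

    # functional expression
    diff_stats_scope: str = "mdg"  # "mdg" or "flagged"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.thresholds = tuple(float(t) for t in config.thresholds)
        return config

    def cutoffs(self) -> screen.CascadeCutoffs:
        return screen.CascadeCutoffs(self.q_ks2, self.q_ksnorm, self.q_f, self.q_loc)


def _load_matrices(config: PipelineConfig):
    if config.expression_c and config.expression_e:
        return io.read_expression_pair(config.expression_c, config.expression_e)
    if config.expression and config.groups:
        return io.read_expression(config.expression, config.groups)
    raise ValueError(
        "config must give either expression+groups or expression_c+expression_e"
    )


def _stage(name, t0, **info):
    details = ", ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, details)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write results under ``config.out_dir``.

    Returns a bundle with the in-memory results: screen table, degree
    profile, separability (observed + null), MD-G ranking, and — when a
    GMT file is configured — enrichment clusters and function-level
    expression. Outputs are deterministic given the config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": asdict(config)}

    t0 = time.perf_counter()
    matrix_c, matrix_e = _load_matrices(config)
    _stage("load", t0, genes=matrix_c.shape[0],
           samples_c=matrix_c.shape[1], samples_e=matrix_e.shape[1])

    t0 = time.perf_counter()
    records = screen.screen_genes(
        matrix_c, matrix_e, config.cutoffs(),
        fdr_scope=config.fdr_scope,
        normality_rule=config.normality_rule,
        lilliefors=config.lilliefors,
    )
    flagged = screen.flagged_genes(records)
    records.to_csv(out / "screen_table.tsv", sep="\t", index=False)
    (out / "flagged_genes.txt").write_text("".join(g + "\n" for g in flagged))
    bundle["screen"] = records
    bundle["flagged"] = flagged
    _stage("screen", t0, flagged=len(flagged))

    if len(flagged) < 2:
        log.warning("fewer than 2 flagged genes; network stages skipped")
        return bundle

    t0 = time.perf_counter()
    profile = degree.degree_sweep(
        matrix_c.loc[flagged], matrix_e.loc[flagged], config.thresholds
    )
    profile.average_table().to_csv(out / "average_degree.tsv", sep="\t")
    observed = degree.separability(profile)
    null = degree.null_separability_probability(
        n_genes=len(flagged),
        n_samples_c=matrix_c.shape[1],
        n_samples_e=matrix_e.shape[1],
        thresholds=config.thresholds,
        n_replicates=config.null_replicates,
        seed=config.seed,
        model=config.null_model,
        data=(
            _pd.concat([matrix_c.loc[flagged], matrix_e.loc[flagged]], axis=1)
            if config.null_model == "label-permutation"
            else None
        ),
    )
    summary = {
        "separable": observed.separable,
        "direction": observed.direction,
        "null_probability": null.null_probability,
        "standard_error": null.standard_error,
        "confidence": null.confidence,
        "n_replicates": null.n_replicates,
        "model": null.model,
        "seed": config.seed,
    }
    (out / "separability.json").write_text(json.dumps(summary, indent=2) + "\n")
    bundle["profile"] = profile
    bundle["separability"] = observed
    bundle["null"] = null
    _stage("degree", t0, separable=observed.separable,
           null_probability=null.null_probability)

    t0 = time.perf_counter()
    ranking = degree.md_scores(profile)
    mdg = degree.top_k(ranking, min(config.k, len(ranking.table)))
    ranking.table.to_csv(out / "degree_scores.tsv", sep="\t", index=False)
    (out / "mdg_list.txt").write_text("".join(g + "\n" for g in mdg))
    bundle["ranking"] = ranking
    bundle["mdg"] = mdg
    _stage("mdg", t0, k=len(mdg))

    functions = None
    if config.gmt:
        t0 = time.perf_counter()
        collection = io.read_gmt(config.gmt)
        query = [g for g in mdg if g in collection.universe]
        if query:
            table = enrichment.enrich(
                query, collection,
                p_max=config.p_max,
                min_count=config.min_count,
                min_factor=config.min_factor,
            )
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            bundle["enrichment"] = table
            if table["retained"].any():
                clusters = enrichment.cluster_terms(
                    table, collection, query,
                    similarity_cut=config.similarity_cut,
                )
                rows = [
                    {
                        "cluster": i + 1,
                        "representative": c.representative,
                        "members": ",".join(c.members),
                    }
                    for i, c in enumerate(clusters)
                ]
                _pd.DataFrame(rows).to_csv(
                    out / "clusters.tsv", sep="\t", index=False
                )
                bundle["clusters"] = clusters
                overlap = dict(
                    zip(table["term"], (g.split(",") for g in table["genes"]))
                )
                functions = {
                    f"P{i + 1}": overlap[c.representative]
                    for i, c in enumerate(clusters)
                    if overlap.get(c.representative)
                }
            _stage("enrich", t0, terms=len(collection),
                   retained=int(table["retained"].sum()))
        else:
            log.warning("no MD-G appears in the GMT universe; enrichment skipped")
    else:
        log.info("stage=enrich skipped (no GMT configured)")

    t0 = time.perf_counter()
    if functions:
        levels = funclevel.function_levels(functions, matrix_c, matrix_e)
        levels.to_csv(out / "function_levels.tsv", sep="\t", index=False)
        bundle["function_levels"] = levels
    stats_genes = mdg if config.diff_stats_scope == "mdg" else flagged
    stats = funclevel.diff_stats(matrix_c, matrix_e, stats_genes)
    (out / "diff_stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    bundle["diff_stats"] = stats
    _stage("funclevel", t0, genes=len(stats_genes))

    return bundle
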