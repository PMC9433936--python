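"""End-to-end orchestration of the filtering pipeline.

Stages: QC -> normalize -> HVG -> PCA/SNN/UMAP -> score -> granulate ->
reassign -> aggregate -> threshold -> call -> filter.  Each stage draws
its randomness from a seed derived from the global seed and the stage
name, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genescore, granulate, preprocess, stresscall
from .config import RunConfig, stage_seed
from .matrix_io import CountMatrix, GeneSet

__all__ = ["PipelineResult", "run_pipeline", "format_report"]


@dataclass
class PipelineResult:
    qc_report: preprocess.QCReport
    norm: preprocess.NormMatrix
    hvg: np.ndarray
    embeddings: preprocess.Embeddings
    snn: preprocess.SnnGraph
    scores: genescore.ScoreTable
    partition: granulate.GranulePartition
    granule_scores: stresscall.GranuleScoreTable
    fits: list[stresscall.ThresholdFit]
    calls: stresscall.StressCall
    filtered: CountMatrix
    config: RunConfig = None
    report: dict = field(default_factory=dict)


def _apply_directions(sets: list[GeneSet], cfg: RunConfig) -> list[GeneSet]:
    """Override set directions from the config's score specs, if given."""
    if not cfg.scores:
        return sets
    wanted = {s.name: s.direction for s in cfg.scores}
    missing = set(wanted) - {g.name for g in sets}
    if missing:
        from .errors import ParameterError

        raise ParameterError(f"config requests unknown gene sets: {sorted(missing)}")
    out = []
    for g in sets:
        if g.name in wanted:
            out.append(GeneSet(g.name, list(g.genes), wanted[g.name], g.description))
    return out


def run_pipeline(
    counts: CountMatrix,
    gene_sets: list[GeneSet],
    cfg: RunConfig,
) -> PipelineResult:
    """Run every stage on an in-memory count matrix and return all
    intermediate artifacts plus a plain-dict report."""
    sets = _apply_directions(gene_sets, cfg)

    kept, qc_report = preprocess.qc_filter(
        counts,
        cfg.min_genes,
        cfg.max_mito_frac,
        cfg.max_ribo_frac,
        mito_prefixes=cfg.mito_prefixes,
        ribo_prefixes=cfg.ribo_prefixes,
    )
    norm = preprocess.normalize(kept)
    hvg = preprocess.select_hvg(norm, min(cfg.n_hvg, norm.n_genes))
    embeddings, snn = preprocess.embed(norm, hvg, cfg, compute_umap3=True)

    scores = genescore.score_all(norm, sets, cfg)

    _, partition = granulate.auto_resolution(
        snn,
        cfg.lower_median,
        cfg.upper_median,
        stage_seed(cfg.seed, "cluster"),
        max_iter=cfg.max_search_iter,
        backend=cfg.clustering,
        cell_ids=norm.cell_ids,
    )
    partition = granulate.reassign_small(partition, embeddings.umap3, cfg.min_granule)

    granule_scores = stresscall.aggregate(scores, partition)
    fits = []
    for gs in sets:
        fit = stresscall.fit_threshold(
            granule_scores.values[gs.name], cfg.quantile,
            name=gs.name, direction=gs.direction,
        )
        if gs.name in cfg.manual_thresholds:
            fit = fit.with_threshold(cfg.manual_thresholds[gs.name])
        fits.append(fit)

    if cfg.mode == "single_cell":
        cell_fits = [
            stresscall.fit_threshold(
                scores.scores[gs.name], cfg.quantile,
                name=gs.name, direction=gs.direction,
            )
            for gs in sets
        ]
        calls = stresscall.single_cell_call(scores, cell_fits)
    else:
        calls = stresscall.combine_and_call(granule_scores, fits, partition)
    filtered = stresscall.filter_cells(kept, calls)

    sizes = np.unique(partition.labels, return_counts=True)[1]
    report = {
        "n_cells_input": counts.n_cells,
        "n_cells_after_qc": kept.n_cells,
        "resolution": partition.resolution,
        "n_granules": int(partition.n_granules),
        "median_granule_size": float(np.median(sizes)),
        "min_granule_size": int(sizes.min()),
        "thresholds": {
            f.name: {"direction": f.direction, "m": f.m, "s": f.s, "t": f.t,
                     "q": f.q, "source": f.source}
            for f in fits
        },
        "stressed_fraction": calls.stressed_fraction,
        "n_stressed": int(calls.cell_table["is_stressed"].sum()),
        "n_kept": filtered.n_cells,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }
    return PipelineResult(
        qc_report=qc_report,
        norm=norm,
        hvg=hvg,
        embeddings=embeddings,
        snn=snn,
        scores=scores,
        partition=partition,
        granule_scores=granule_scores,
        fits=fits,
        calls=calls,
        filtered=filtered,
        config=cfg,
        report=report,
    )


def format_report(report: dict) -> str:
    lines = [
        "granufilt run report",
        "====================",
        f"cells in            : {report['n_cells_input']}",
        f"cells after QC      : {report['n_cells_after_qc']}",
        f"clustering resolution: {report['resolution']:g}",
        f"granules            : {report['n_granules']}",
        f"median granule size : {report['median_granule_size']:g}",
        f"min granule size    : {report['min_granule_size']}",
        "thresholds:",
    ]
    for name, th in report["thresholds"].items():
        lines.append(
            f"  {name} ({th['direction']}, {th['source']}): "
            f"m={th['m']:.4f} s={th['s']:.4f} t={th['t']:.4f} q={th['q']}"
        )
    lines += [
        f"stressed cells      : {report['n_stressed']} "
        f"({100 * report['stressed_fraction']:.1f}%)",
        f"cells kept          : {report['n_kept']}",
        f"seed                : {report['seed']}",
        f"config hash         : {report['config_hash']}",
    ]
    return "\n".join(lines) + "\n"
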