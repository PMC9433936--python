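"""Shared fixtures.

The full-scale pipeline run (20,000 cells) is expensive, so it is a
session fixture computed once and shared by every test that inspects
end-to-end behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from granufilt import CountMatrix, NormMatrix, RunConfig, run_pipeline, synthsim


def make_counts(dense, cell_prefix="c", gene_prefix="g") -> CountMatrix:
    dense = np.asarray(dense)
    n, g = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        np.array([f"{cell_prefix}{i:04d}" for i in range(n)], dtype=object),
        np.array([f"{gene_prefix}{j:04d}" for j in range(g)], dtype=object),
    )


def make_norm(dense, cell_prefix="c", gene_prefix="g") -> NormMatrix:
    dense = np.asarray(dense, dtype=float)
    n, g = dense.shape
    return NormMatrix(
        sp.csr_matrix(dense),
        np.array([f"{cell_prefix}{i:04d}" for i in range(n)], dtype=object),
        np.array([f"{gene_prefix}{j:04d}" for j in range(g)], dtype=object),
    )


@pytest.fixture(scope="session")
def bundle20k():
    return synthsim.default_fixture(seed=1)


@pytest.fixture(scope="session")
def pipeline20k(bundle20k):
    return run_pipeline(bundle20k.counts, bundle20k.gene_sets, RunConfig(seed=1))


def run_granular_and_single_cell(stress_lfc: float, seed: int = 11, n_cells: int = 4000):
    """Scaled-down end-to-end run returning (sens, spec) per calling mode.

    Skips UMAP/reassignment (no small granules are needed for calling)
    so the effect-size grid stays cheap; single-cell mode is evaluated
    at a quantile chosen to match the granular stressed-cell count.
    """
    from granufilt import (
        genescore,
        granulate,
        preprocess,
        stresscall,
    )
    from granufilt.config import stage_seed

    bundle = synthsim.generate(
        synthsim.SynthSpec(n_cells=n_cells, stress_lfc=stress_lfc, seed=seed)
    )
    cfg = RunConfig(lower_median=50, upper_median=100, min_granule=15, seed=seed)
    kept, _ = preprocess.qc_filter(
        bundle.counts, cfg.min_genes, cfg.max_mito_frac, cfg.max_ribo_frac
    )
    norm = preprocess.normalize(kept)
    hvg = preprocess.select_hvg(norm, min(cfg.n_hvg, norm.n_genes))
    pca = preprocess.compute_pca(norm, hvg, cfg.n_pcs, stage_seed(cfg.seed, "pca"))
    snn = preprocess.knn_snn(pca, cfg.knn_k, cfg.snn_prune)
    scores = genescore.score_all(norm, bundle.gene_sets, cfg)
    _, part = granulate.auto_resolution(
        snn, cfg.lower_median, cfg.upper_median,
        stage_seed(cfg.seed, "cluster"), cell_ids=norm.cell_ids,
    )
    gt = stresscall.aggregate(scores, part)
    fits = [
        stresscall.fit_threshold(gt.values[g.name], cfg.quantile,
                                 name=g.name, direction=g.direction)
        for g in bundle.gene_sets
    ]
    granular = stresscall.combine_and_call(gt, fits, part)

    idx = pd.Index(bundle.counts.cell_ids).get_indexer(norm.cell_ids)
    truth = bundle.truth.stressed[idx]

    def metrics(call):
        called = call.cell_table["is_stressed"].loc[norm.cell_ids].to_numpy()
        tp = (truth & called).sum()
        fn = (truth & ~called).sum()
        tn = (~truth & ~called).sum()
        fp = (~truth & called).sum()
        return tp / (tp + fn), tn / (tn + fp)

    n_granular = int(granular.cell_table["is_stressed"].sum())
    cell_fits = [
        stresscall.fit_threshold(scores.scores[g.name], cfg.quantile,
                                 name=g.name, direction=g.direction)
        for g in bundle.gene_sets
    ]
    lo, hi = 0.5, 1 - 1e-9  # bisect the quantile to match the call count
    for _ in range(40):
        mid = (lo + hi) / 2
        n = int(
            stresscall.single_cell_call(scores, cell_fits, quantile_override=mid)
            .cell_table["is_stressed"].sum()
        )
        if n > n_granular:
            lo = mid
        else:
            hi = mid
    sc = stresscall.single_cell_call(scores, cell_fits, quantile_override=(lo + hi) / 2)
    return {"granular": metrics(granular), "single_cell": metrics(sc)}


@pytest.fixture(scope="session")
def lfc_grid_runs():
    return {lfc: run_granular_and_single_cell(lfc) for lfc in (0.5, 0.75, 1.5)}


@pytest.fixture(scope="session")
def recovery20k(bundle20k, pipeline20k):
    """Ground-truth confusion counts of the end-to-end run."""
    res = pipeline20k
    idx = pd.Index(bundle20k.counts.cell_ids).get_indexer(res.norm.cell_ids)
    truth = bundle20k.truth.stressed[idx]
    called = res.calls.cell_table["is_stressed"].loc[res.norm.cell_ids].to_numpy()
    tp = int((truth & called).sum())
    fn = int((truth & ~called).sum())
    tn = int((~truth & ~called).sum())
    fp = int((~truth & called).sum())
    return {
        "truth": truth,
        "called": called,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "called_fraction": called.mean(),
        "planted_fraction": bundle20k.spec.fraction_stressed,
    }
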