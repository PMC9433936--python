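"""Per-cell pathway activity scores with binned control genes.

The score of a gene set in a cell is the mean log-normalized expression
of the target genes minus the mean expression of an expression-matched
control pool.  Controls matter because expression level drives
expression variability: comparing a target set against random genes of
similar mean expression cancels cell-to-cell differences in depth and
quality.

Algorithm (per gene set):

1. compute each gene's mean log-normalized expression over all cells;
2. partition all genes into ``n_bins`` equal-frequency bins of that mean
   (rank-based; ties broken by gene-symbol order);
3. for every target gene, sample ``n_ctrl`` genes uniformly from its
   bin, excluding the target set itself (a pathway gene never controls
   the pathway) — without replacement when the bin is large enough,
   with replacement otherwise; the control pool is the union of all
   samples;
4. score(cell) = mean expression of target genes - mean expression of
   the control pool, in that cell.

Sampling iterates target genes in set order and draws from bin members
sorted by (mean, symbol) rank, so a fixed seed reproduces scores
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ParameterError, ScoringError
from .matrix_io import GeneSet
from .preprocess import NormMatrix

__all__ = ["ScoreTable", "intersect_set", "module_score", "score_all"]


@dataclass
class ScoreTable:
    """Per-cell scores, one column per gene set, cells in matrix order."""

    scores: pd.DataFrame  # index = cell_ids, columns = score names
    provenance: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.scores.columns)


def intersect_set(gs: GeneSet, nm: NormMatrix, min_set_size: int = 5) -> GeneSet:
    """Restrict a gene set to genes detected (nonzero total) in ``nm``.

    Dropped symbols are recorded on the returned set for audit logging.
    """
    totals = np.asarray(nm.values.sum(axis=0)).ravel()
    detected = {g for g, t in zip(nm.gene_ids, totals) if t > 0}
    kept = [g for g in gs.genes if g in detected]
    dropped = [g for g in gs.genes if g not in detected]
    if len(kept) < min_set_size:
        raise ScoringError(
            f"gene set {gs.name!r}: only {len(kept)} of {len(gs.genes)} genes "
            f"detected (need >= {min_set_size}); dropped: {dropped[:10]}"
        )
    return GeneSet(
        name=gs.name,
        genes=kept,
        direction=gs.direction,
        description=gs.description,
        dropped=dropped,
    )


def _expression_bins(nm: NormMatrix, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency bin label per gene, plus the rank order used.

    Genes are ranked by mean expression with gene-symbol order breaking
    ties, then cut into ``n_bins`` near-equal-size bins.
    """
    mean = np.asarray(nm.values.mean(axis=0)).ravel()
    order = np.lexsort((nm.gene_ids.astype(str), mean))
    ranks = np.empty(len(order), dtype=np.int64)
    ranks[order] = np.arange(len(order))
    bins = (ranks * n_bins) // len(order)
    return bins, mean


def module_score(
    nm: NormMatrix,
    gs: GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score of ``gs`` for every cell of ``nm``.

    ``gs`` must already be intersected with detected genes
    (see :func:`intersect_set`); undetected members raise.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ParameterError("n_bins and n_ctrl must be >= 1")
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    missing = [g for g in gs.genes if g not in gene_index]
    if missing:
        raise ParameterError(
            f"gene set {gs.name!r} contains genes absent from the matrix "
            f"(call intersect_set first): {missing[:10]}"
        )
    target_idx = np.array([gene_index[g] for g in gs.genes], dtype=np.int64)
    totals = np.asarray(nm.values.sum(axis=0)).ravel()
    if np.any(totals[target_idx] == 0):
        undet = [g for g in gs.genes if totals[gene_index[g]] == 0]
        raise ParameterError(
            f"gene set {gs.name!r} contains undetected genes "
            f"(call intersect_set first): {undet[:10]}"
        )

    bins, _ = _expression_bins(nm, n_bins)
    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }

    rng = np.random.default_rng(seed)
    control: set[int] = set()
    for t in target_idx:  # set order: reproducible for a fixed seed
        pool = members[bins[t]]
        pool = pool[~np.isin(pool, target_idx)]  # targets never control
        if len(pool) == 0:
            continue
        replace = len(pool) < n_ctrl
        control.update(rng.choice(pool, size=n_ctrl, replace=replace).tolist())
    control_idx = np.array(sorted(control), dtype=np.int64)
    if len(control_idx) == 0:
        raise ScoringError(f"gene set {gs.name!r}: empty control pool")

    target_mean = np.asarray(nm.values[:, target_idx].mean(axis=1)).ravel()
    control_mean = np.asarray(nm.values[:, control_idx].mean(axis=1)).ravel()
    return target_mean - control_mean


def score_all(nm: NormMatrix, sets: list[GeneSet], cfg: RunConfig) -> ScoreTable:
    """Score every gene set; one column per set, deterministic per seed.

    Per-set seeds are derived from the set name so adding or reordering
    sets never changes another set's scores.
    """
    from .config import stage_seed

    if not sets:
        raise ParameterError("no gene sets given")
    names = [gs.name for gs in sets]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate gene set names: {names}")

    columns: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    failures: list[str] = []
    for gs in sets:
        try:
            inter = intersect_set(gs, nm, cfg.min_set_size)
            sd = stage_seed(cfg.seed, f"score:{gs.name}")
            columns[gs.name] = module_score(nm, inter, cfg.n_bins, cfg.n_ctrl, sd)
            provenance[gs.name] = {
                "direction": inter.direction,
                "n_genes": len(inter.genes),
                "dropped": inter.dropped,
                "seed": sd,
            }
        except ScoringError as exc:
            failures.append(str(exc))
    if failures:
        raise ScoringError(
            f"{len(failures)} gene set(s) could not be scored:\n" + "\n".join(failures)
        )
    df = pd.DataFrame(columns, index=nm.cell_ids)
    return ScoreTable(scores=df, provenance=provenance)
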