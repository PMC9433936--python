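"""Granule-level score aggregation, automatic thresholds, stress calls.

The thresholding model: granule scores are averages over ~100+ cells,
so by the central limit theorem the scores of *non-stressed* granules
are approximately Gaussian.  Stressed granules contaminate only the
upper tail (stress scores are elevated, and stressed cells are the
minority), so the Gaussian's location is estimated by the median of all
granule scores and its scale from the lower half only: the
root-mean-square deviation about the median of the scores strictly
below it.  The threshold is the theoretical ``q``-quantile (default
99%) of that fitted normal:

    t = m + z_q * s,  m = median,  s = sqrt(mean_{x < m} (x - m)^2)

Granules whose positive-score (glycolysis, ER-stress) exceeds its
threshold are stressed, unless a negative-score (e.g. gliogenesis)
also exceeds its own threshold, which vetoes the call and protects
cell types with a high native score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import GranufiltError, ParameterError
from .genescore import ScoreTable
from .granulate import GranulePartition
from .matrix_io import CountMatrix
from .preprocess import NormMatrix

__all__ = [
    "GranuleScoreTable",
    "ThresholdFit",
    "StressCall",
    "aggregate",
    "fit_threshold",
    "combine_and_call",
    "single_cell_call",
    "filter_cells",
]


@dataclass
class GranuleScoreTable:
    """Mean score of each granule's member cells, one row per granule."""

    values: pd.DataFrame  # index = granule id, columns = score names
    cell_counts: pd.Series  # index = granule id


@dataclass
class ThresholdFit:
    name: str
    direction: str  # positive selects stress, negative vetoes
    m: float  # location = median of granule scores
    s: float  # scale = lower-tail RMS about the median
    q: float  # Gaussian quantile
    t: float  # threshold = m + z_q * s
    source: str = "auto"  # or "manual"

    def with_quantile(self, q: float) -> "ThresholdFit":
        """Re-derive the threshold at a different quantile from the same fit."""
        if not 0.0 < q < 1.0:
            raise ParameterError(f"quantile must be in (0, 1), got {q}")
        return replace(self, q=q, t=self.m + norm.ppf(q) * self.s)

    def with_threshold(self, t: float) -> "ThresholdFit":
        return replace(self, t=float(t), source="manual")


@dataclass
class StressCall:
    """Per-cell stress labels plus the thresholds that produced them.

    ``cell_table`` is indexed by cell id with columns ``granule_id``,
    one column per score (the granule-level value in granular mode, the
    raw cell value in single-cell mode) and ``is_stressed``.
    """

    cell_table: pd.DataFrame
    granule_stressed: pd.Series | None  # None in single-cell mode
    fits: list[ThresholdFit]
    mode: str  # "granular" | "single_cell"

    @property
    def stressed_cells(self) -> np.ndarray:
        return self.cell_table.index[self.cell_table["is_stressed"]].to_numpy()

    @property
    def stressed_fraction(self) -> float:
        return float(self.cell_table["is_stressed"].mean())


def aggregate(scores: ScoreTable, p: GranulePartition) -> GranuleScoreTable:
    """Mean score per granule (the cell-number-normalized granule score)."""
    if len(scores.scores) != p.n_cells:
        raise GranufiltError(
            f"score table has {len(scores.scores)} cells but the partition "
            f"covers {p.n_cells}"
        )
    if p.cell_ids is not None and not np.array_equal(
        np.asarray(scores.scores.index), np.asarray(p.cell_ids)
    ):
        raise GranufiltError("score table and partition disagree on cell ids/order")
    g = pd.Series(p.labels, index=scores.scores.index, name="granule_id")
    grouped = scores.scores.groupby(g)
    return GranuleScoreTable(values=grouped.mean(), cell_counts=grouped.size())


def fit_threshold(
    g_scores: np.ndarray | pd.Series,
    q: float = 0.99,
    *,
    name: str = "",
    direction: str = "positive",
) -> ThresholdFit:
    """Fit the contamination-robust Gaussian upper threshold.

    Location ``m`` is the median of the scores.  Scale ``s`` is the RMS
    deviation about ``m`` of the scores strictly below ``m`` (population
    divisor = their count; 0 if none are below).  Threshold
    ``t = m + z_q * s`` with ``z_q`` the standard-normal ``q``-quantile.
    """
    x = np.asarray(g_scores, dtype=float)
    if len(x) < 3:
        raise ParameterError(f"need >= 3 granule scores, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise GranufiltError("non-finite granule scores")
    if not 0.0 < q < 1.0:
        raise ParameterError(f"quantile must be in (0, 1), got {q}")
    m = float(np.median(x))
    lower = x[x < m]
    s = float(np.sqrt(np.mean((lower - m) ** 2))) if len(lower) else 0.0
    t = m + norm.ppf(q) * s
    return ThresholdFit(name=name, direction=direction, m=m, s=s, q=q, t=float(t))


def _combine(values: pd.DataFrame, fits: list[ThresholdFit]) -> pd.Series:
    """Row is stressed iff any positive score exceeds its threshold and
    no negative score exceeds its own (strict inequalities)."""
    if not fits:
        raise ParameterError("no threshold fits given")
    missing = [f.name for f in fits if f.name not in values.columns]
    if missing:
        raise GranufiltError(f"fits reference unknown scores: {missing}")
    positives = [f for f in fits if f.direction == "positive"]
    negatives = [f for f in fits if f.direction == "negative"]
    if not positives:
        raise ParameterError("at least one positive-direction fit is required")
    pos_hit = np.zeros(len(values), dtype=bool)
    for f in positives:
        pos_hit |= values[f.name].to_numpy() > f.t
    neg_hit = np.zeros(len(values), dtype=bool)
    for f in negatives:
        neg_hit |= values[f.name].to_numpy() > f.t
    return pd.Series(pos_hit & ~neg_hit, index=values.index, name="is_stressed")


def combine_and_call(
    gt: GranuleScoreTable,
    fits: list[ThresholdFit],
    p: GranulePartition,
) -> StressCall:
    """Granular-mode call: threshold the granule scores, broadcast the
    granule verdict to every member cell."""
    granule_stressed = _combine(gt.values, fits)
    cell_index = (
        pd.Index(p.cell_ids) if p.cell_ids is not None else pd.RangeIndex(p.n_cells)
    )
    table = gt.values.loc[p.labels].set_index(cell_index)
    table.insert(0, "granule_id", p.labels)
    table["is_stressed"] = granule_stressed.loc[p.labels].to_numpy()
    return StressCall(
        cell_table=table, granule_stressed=granule_stressed, fits=fits, mode="granular"
    )


def single_cell_call(
    scores: ScoreTable,
    fits_on_cells: list[ThresholdFit],
    quantile_override: float | None = None,
) -> StressCall:
    """Single-cell mode: identical threshold/combination logic applied to
    raw per-cell scores (no granule averaging).

    ``fits_on_cells`` must have been fitted on the per-cell scores.
    ``quantile_override`` replaces each fit's quantile, re-deriving the
    thresholds from the stored location/scale — used to match a target
    stressed-cell count when comparing against granular mode.
    """
    fits = fits_on_cells
    if quantile_override is not None:
        fits = [f.with_quantile(quantile_override) for f in fits]
    table = scores.scores.copy()
    table["is_stressed"] = _combine(scores.scores, fits)
    table.insert(0, "granule_id", np.arange(len(table)))  # each cell its own unit
    return StressCall(
        cell_table=table, granule_stressed=None, fits=fits, mode="single_cell"
    )


def filter_cells(m: CountMatrix | NormMatrix, calls: StressCall):
    """Drop stressed cells from a count or normalized matrix.

    Any embedding or graph computed before filtering is invalid for the
    returned matrix and must be recomputed; this function deliberately
    returns only the matrix so stale scaffolds cannot be reused.
    """
    ids = pd.Index(m.cell_ids)
    missing = ids.difference(calls.cell_table.index)
    if len(missing):
        raise GranufiltError(
            f"stress calls missing for {len(missing)} cells, e.g. {list(missing[:5])}"
        )
    stressed = calls.cell_table["is_stressed"].reindex(ids).to_numpy()
    keep = ~stressed
    if not keep.any():
        raise GranufiltError("every cell is flagged stressed; refusing empty output")
    return m.subset_cells(keep)
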