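"""Partition cells into granules by resolution-searched graph clustering.

A granule is a small cluster of roughly 100-200 cells used as the unit
of score aggregation: large enough that the mean of its members' scores
is statistically stable, small enough to stay transcriptionally
homogeneous.  The clustering resolution needed to hit that size depends
on the dataset, so it is searched automatically, and granules that end
up under ``min_granule`` cells are dissolved into the nearest adequate
granule in 3-D UMAP space.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .errors import GranufiltError, ParameterError
from .preprocess import SnnGraph

__all__ = ["GranulePartition", "cluster_at", "auto_resolution", "reassign_small"]


@dataclass
class GranulePartition:
    labels: np.ndarray  # per-cell granule id, contiguous ints from 0
    resolution: float
    cell_ids: np.ndarray | None = None
    reassigned: np.ndarray = field(default=None)  # per-cell bool

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.reassigned is None:
            self.reassigned = np.zeros(len(self.labels), dtype=bool)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def median_size(self) -> float:
        return float(np.median(np.unique(self.labels, return_counts=True)[1]))

    @property
    def n_granules(self) -> int:
        return len(np.unique(self.labels))


def _to_igraph(snn: SnnGraph) -> ig.Graph:
    coo = snn.weights.tocoo()
    mask = coo.row < coo.col  # undirected: upper triangle once
    edges = np.column_stack([coo.row[mask], coo.col[mask]])
    g = ig.Graph(n=snn.weights.shape[0], edges=edges.tolist())
    g.es["weight"] = coo.data[mask].tolist()
    return g


def _cluster(g: ig.Graph, resolution: float, seed: int, backend: str) -> np.ndarray:
    if backend == "louvain":
        random.seed(seed)  # python-igraph draws from the stdlib RNG
        part = g.community_multilevel(weights="weight", resolution=resolution)
        return np.asarray(part.membership, dtype=np.int64)
    if backend == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
        return np.asarray(part.membership, dtype=np.int64)
    raise ParameterError(f"unknown clustering backend {backend!r}")


def cluster_at(
    snn: SnnGraph,
    resolution: float,
    seed: int = 0,
    *,
    backend: str = "louvain",
    cell_ids: np.ndarray | None = None,
) -> GranulePartition:
    """Modularity community detection on the SNN graph at one resolution."""
    if resolution <= 0:
        raise ParameterError(f"resolution must be positive, got {resolution}")
    n = snn.weights.shape[0]
    if n == 0 or snn.weights.nnz == 0:
        raise GranufiltError("SNN graph has no edges; cannot cluster")
    g = _to_igraph(snn)
    labels = _cluster(g, resolution, seed, backend)
    return GranulePartition(labels=labels, resolution=resolution, cell_ids=cell_ids)


def auto_resolution(
    snn: SnnGraph,
    lower_median: int = 100,
    upper_median: int = 200,
    seed: int = 0,
    *,
    max_iter: int = 30,
    backend: str = "louvain",
    cell_ids: np.ndarray | None = None,
) -> tuple[float, GranulePartition]:
    """Search the clustering resolution whose median granule size falls
    in ``[lower_median, upper_median]`` (closed interval).

    Strategy: start at resolution 1 and expand geometrically (doubling
    when granules are too large, halving when too small) until the
    target band is hit or bracketed, then bisect the bracket in log
    space.  Median size decreases with resolution, so the bracket keeps
    a low resolution with median above the band and a high resolution
    with median below it.  At most ``max_iter`` clusterings are run.
    """
    if not lower_median < upper_median:
        raise ParameterError("lower_median must be < upper_median")
    n = snn.weights.shape[0]
    if n < lower_median:
        raise ParameterError(
            f"graph has {n} cells, fewer than lower_median={lower_median}"
        )

    g = _to_igraph(snn)
    attempts: list[tuple[float, float]] = []

    def median_at(res: float) -> tuple[float, np.ndarray]:
        labels = _cluster(g, res, seed, backend)
        med = float(np.median(np.unique(labels, return_counts=True)[1]))
        attempts.append((res, med))
        return med, labels

    lo_res = hi_res = None  # lo_res: median too big; hi_res: median too small
    res = 1.0
    for _ in range(max_iter):
        med, labels = median_at(res)
        if lower_median <= med <= upper_median:
            return res, GranulePartition(labels=labels, resolution=res, cell_ids=cell_ids)
        if med > upper_median:
            lo_res = res
        else:
            hi_res = res
        if lo_res is None:
            res /= 2.0
        elif hi_res is None:
            res *= 2.0
        else:
            res = math.sqrt(lo_res * hi_res)  # log-space bisection
    raise GranufiltError(
        f"no resolution with median granule size in [{lower_median}, "
        f"{upper_median}] found in {max_iter} attempts; tried "
        + ", ".join(f"res={r:g} -> median={m:g}" for r, m in attempts)
    )


def reassign_small(
    p: GranulePartition,
    umap3: np.ndarray,
    min_granule: int = 30,
) -> GranulePartition:
    """Dissolve granules smaller than ``min_granule`` cells.

    Recipient granules are those already at or above the minimum size;
    their centroids (mean member 3-D UMAP coordinates) are computed once
    before any transfer, then every cell of an under-sized granule moves
    to the recipient with the nearest centroid (Euclidean distance).
    Donor granule ids disappear and labels are re-compacted to 0..G-1.
    """
    umap3 = np.asarray(umap3, dtype=float)
    if umap3.shape[0] != p.n_cells or umap3.shape[1] != 3:
        raise ParameterError(
            f"umap3 must be {p.n_cells} x 3, got {umap3.shape}"
        )
    ids, counts = np.unique(p.labels, return_counts=True)
    recipients = ids[counts >= min_granule]
    if len(recipients) == 0:
        raise GranufiltError(
            f"no granule reaches min_granule={min_granule}; "
            "lower the clustering resolution or the size floor"
        )
    donors = set((ids[counts < min_granule]).tolist())
    labels = p.labels.copy()
    reassigned = p.reassigned.copy()
    if donors:
        centroids = np.stack(
            [umap3[labels == r].mean(axis=0) for r in recipients]
        )  # frozen before any transfer
        donor_cells = np.flatnonzero(np.isin(labels, list(donors)))
        d2 = (
            (umap3[donor_cells, None, :] - centroids[None, :, :]) ** 2
        ).sum(axis=2)
        labels[donor_cells] = recipients[np.argmin(d2, axis=1)]
        reassigned[donor_cells] = True
    # compact ids to 0..G-1, preserving order
    remap = {old: new for new, old in enumerate(np.unique(labels))}
    labels = np.array([remap[v] for v in labels], dtype=np.int64)
    return GranulePartition(
        labels=labels,
        resolution=p.resolution,
        cell_ids=p.cell_ids,
        reassigned=reassigned,
    )
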