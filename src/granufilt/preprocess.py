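"""QC filtering, normalization, and the embedding/graph scaffold.

The granulation step needs a shared-nearest-neighbor (SNN) graph and a
3-D UMAP embedding; both are derived from a PCA of scaled, highly
variable genes, mirroring the standard Seurat-style workflow: CP10K
log-normalization, log-VMR variable-gene selection, per-gene z-scaling,
PCA, kNN in PC space, Jaccard SNN weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import RunConfig
from .errors import GranufiltError, ParameterError
from .matrix_io import CountMatrix

__all__ = [
    "NormMatrix",
    "Embeddings",
    "SnnGraph",
    "QCReport",
    "qc_filter",
    "normalize",
    "select_hvg",
    "embed",
]

CP10K_TOTAL = 10_000.0


@dataclass
class NormMatrix:
    """Log-normalized expression: ``log1p(10,000 * count / cell_total)``."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "NormMatrix":
        return NormMatrix(self.values[mask], self.cell_ids[mask], self.gene_ids)


@dataclass
class Embeddings:
    pca: np.ndarray  # cells x n_pcs
    umap3: np.ndarray | None = None  # cells x 3
    umap2: np.ndarray | None = None  # cells x 2, plotting only


@dataclass
class SnnGraph:
    """Symmetric SNN graph: Jaccard similarity of kNN neighborhoods.

    ``weights[i, j] = |N(i) & N(j)| / |N(i) | N(j)|`` where N(i) is the
    k-nearest-neighbor set of cell i (self included), with entries below
    the prune cutoff removed and no self-loops.
    """

    weights: sp.csr_matrix
    k: int


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_high_mito: int
    removed_high_ribo: int
    rules: dict = field(default_factory=dict)


def _prefix_mask(gene_ids: np.ndarray, prefixes: tuple[str, ...]) -> np.ndarray:
    upper = np.char.upper(gene_ids.astype(str))
    mask = np.zeros(len(upper), dtype=bool)
    for p in prefixes:
        mask |= np.char.startswith(upper, p.upper())
    return mask


def qc_filter(
    m: CountMatrix,
    min_genes: int = 500,
    max_mito: float = 0.20,
    max_ribo: float = 0.30,
    *,
    mito_prefixes: tuple[str, ...] = ("MT-",),
    ribo_prefixes: tuple[str, ...] = ("RPL", "RPS"),
) -> tuple[CountMatrix, QCReport]:
    """Keep cells with > ``min_genes`` detected genes, mitochondrial UMI
    fraction < ``max_mito`` and ribosomal UMI fraction < ``max_ribo``.

    The three rules are conjunctive; the report counts, per rule, how
    many cells violate it (a cell failing two rules is counted in both).
    """
    counts = m.counts
    genes_per_cell = counts.getnnz(axis=1)
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    mito = _prefix_mask(m.gene_ids, mito_prefixes)
    ribo = _prefix_mask(m.gene_ids, ribo_prefixes)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, np.asarray(counts[:, mito].sum(axis=1)).ravel() / np.maximum(totals, 1), 0.0
        )
        ribo_frac = np.where(
            totals > 0, np.asarray(counts[:, ribo].sum(axis=1)).ravel() / np.maximum(totals, 1), 0.0
        )

    ok_genes = genes_per_cell > min_genes
    ok_mito = mito_frac < max_mito
    ok_ribo = ribo_frac < max_ribo
    keep = ok_genes & ok_mito & ok_ribo
    if not keep.any():
        raise GranufiltError(
            "QC removed every cell "
            f"(gene-count rule failed for {int((~ok_genes).sum())}, "
            f"mito rule for {int((~ok_mito).sum())}, "
            f"ribo rule for {int((~ok_ribo).sum())}); relax the thresholds"
        )
    report = QCReport(
        n_input=m.n_cells,
        n_kept=int(keep.sum()),
        removed_low_genes=int((~ok_genes).sum()),
        removed_high_mito=int((~ok_mito).sum()),
        removed_high_ribo=int((~ok_ribo).sum()),
        rules={
            "min_genes": min_genes,
            "max_mito": max_mito,
            "max_ribo": max_ribo,
        },
    )
    return m.subset_cells(keep), report


def normalize(m: CountMatrix) -> NormMatrix:
    """CP10K log-normalization: scale each cell to 10,000 total counts,
    then apply log1p.  All-zero cells stay all-zero (with a warning)."""
    counts = sp.csr_matrix(m.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells have zero total counts", stacklevel=2)
    scale = np.where(zero, 0.0, CP10K_TOTAL / np.maximum(totals, 1e-300))
    values = sp.diags(scale) @ counts
    values.data = np.log1p(values.data)
    return NormMatrix(sp.csr_matrix(values), m.cell_ids.copy(), m.gene_ids.copy())


def _expm1_moments(nm: NormMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and variance of expm1-backtransformed expression."""
    x = nm.values.copy()
    x.data = np.expm1(x.data)
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = x.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    # unbiased sample variance
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(nm: NormMatrix, n: int) -> np.ndarray:
    """Indices of the top-``n`` highly variable genes by log
    variance-to-mean ratio of the expm1-backtransformed expression.

    Undetected genes (zero mean) rank last; ties break by gene-symbol
    order so the selection is deterministic.
    """
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    if n > nm.n_genes:
        raise ParameterError(f"n={n} exceeds gene count {nm.n_genes}")
    mean, var = _expm1_moments(nm)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_vmr = np.where((mean > 0) & (var > 0), np.log(var / mean), -np.inf)
    order = np.lexsort((nm.gene_ids.astype(str), -log_vmr))
    return np.sort(order[:n])


def _scale_genes(dense: np.ndarray) -> np.ndarray:
    """Center and unit-scale each gene; constant genes become zero."""
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (dense - mean) / sd


def compute_pca(nm: NormMatrix, hvg: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    if len(hvg) == 0:
        raise ParameterError("hvg list is empty")
    if n_pcs > min(nm.n_cells, len(hvg)):
        raise ParameterError(
            f"n_pcs={n_pcs} exceeds min(cells={nm.n_cells}, hvg={len(hvg)})"
        )
    dense = np.asarray(nm.values[:, hvg].todense(), dtype=np.float32)
    scaled = _scale_genes(dense)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(scaled).astype(np.float64)


def knn_snn(pca: np.ndarray, k: int, prune: float) -> SnnGraph:
    """Jaccard SNN graph from kNN neighborhoods (self included) in PC space."""
    n = pca.shape[0]
    if k >= n:
        raise ParameterError(f"knn_k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(pca)
    _, idx = nn.kneighbors(pca)  # row i's neighborhood, self at position 0
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=np.float64), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |N(i) & N(j)|
    shared = sp.csr_matrix(shared)
    union = 2.0 * k - shared.data  # |N(i) | N(j)| = 2k - shared
    jac = shared.copy()
    jac.data = shared.data / union
    jac.setdiag(0.0)
    jac.data[jac.data < prune] = 0.0
    jac.eliminate_zeros()
    return SnnGraph(weights=sp.csr_matrix(jac), k=k)


def compute_umap(
    pca: np.ndarray,
    n_components: int,
    seed: int,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
) -> np.ndarray:
    import umap  # deferred: numba JIT import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=n_components,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(pca), dtype=np.float64)


def embed(
    nm: NormMatrix,
    hvg: np.ndarray,
    cfg: RunConfig,
    *,
    compute_umap3: bool = True,
) -> tuple[Embeddings, SnnGraph]:
    """Full scaffold: scaled-gene PCA, kNN/SNN graph, 3-D UMAP.

    The 3-D UMAP is computed by default because small-granule
    reassignment operates in that space; 2-D is opt-in for plotting.
    """
    from .config import stage_seed

    pca = compute_pca(nm, hvg, cfg.n_pcs, stage_seed(cfg.seed, "pca"))
    snn = knn_snn(pca, cfg.knn_k, cfg.snn_prune)
    umap3 = None
    if compute_umap3:
        umap3 = compute_umap(
            pca, 3, stage_seed(cfg.seed, "umap3"), cfg.umap_neighbors, cfg.umap_min_dist
        )
    umap2 = None
    if cfg.umap_2d:
        umap2 = compute_umap(
            pca, 2, stage_seed(cfg.seed, "umap2"), cfg.umap_neighbors, cfg.umap_min_dist
        )
    return Embeddings(pca=pca, umap3=umap3, umap2=umap2), snn
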