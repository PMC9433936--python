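"""Run configuration: every tunable of the pipeline in one dataclass.

Defaults encode the standard workflow: QC keeps cells with > 500
detected genes, < 20% mitochondrial and < 30% ribosomal reads; counts
are CP10K log-normalized; 2,000 highly variable genes feed a 50-PC PCA;
a k=20 shared-nearest-neighbor graph with Jaccard weights (pruned below
1/15) is clustered at an automatically searched resolution targeting a
median granule size of 100-200 cells; granules under 30 cells are
reassigned in 3-D UMAP space; score thresholds use the Gaussian 99%
quantile.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InputError, ParameterError

__all__ = ["ScoreSpec", "RunConfig", "load_config", "stage_seed"]


@dataclass
class ScoreSpec:
    """One requested pathway score: a gene-set name and its direction."""

    name: str
    direction: str = "positive"  # positive selects stress, negative vetoes


@dataclass
class RunConfig:
    # QC
    min_genes: int = 500
    max_mito_frac: float = 0.20
    max_ribo_frac: float = 0.30
    mito_prefixes: tuple[str, ...] = ("MT-",)
    ribo_prefixes: tuple[str, ...] = ("RPL", "RPS")
    # embedding scaffold
    n_hvg: int = 2000
    n_pcs: int = 50
    knn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    umap_2d: bool = False
    # granulation
    lower_median: int = 100
    upper_median: int = 200
    min_granule: int = 30
    max_search_iter: int = 30
    clustering: str = "louvain"  # or "leiden"
    # scoring
    n_bins: int = 25
    n_ctrl: int = 100
    min_set_size: int = 5
    scores: list[ScoreSpec] = field(default_factory=list)
    gmt_path: str | None = None
    # thresholding
    quantile: float = 0.99
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    mode: str = "granular"  # or "single_cell"
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.lower_median < self.upper_median:
            raise ParameterError(
                f"lower_median ({self.lower_median}) must be < upper_median "
                f"({self.upper_median})"
            )
        if not 0.0 < self.quantile < 1.0:
            raise ParameterError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.min_granule < 2:
            raise ParameterError(f"min_granule must be >= 2, got {self.min_granule}")
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ParameterError("n_bins and n_ctrl must be >= 1")
        if self.clustering not in ("louvain", "leiden"):
            raise ParameterError(f"unknown clustering backend {self.clustering!r}")
        if self.mode not in ("granular", "single_cell"):
            raise ParameterError(f"mode must be granular/single_cell, got {self.mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scores"] = [asdict(s) if isinstance(s, ScoreSpec) else s for s in self.scores]
        return d

    # fields each intermediate artifact depends on; used so that e.g. a
    # manual threshold override does not invalidate saved scores
    _QC_FIELDS = (
        "min_genes", "max_mito_frac", "max_ribo_frac", "mito_prefixes",
        "ribo_prefixes",
    )
    _SCOPE_FIELDS = {
        "scoring": _QC_FIELDS + ("n_bins", "n_ctrl", "min_set_size", "seed"),
        "granulate": _QC_FIELDS + (
            "n_hvg", "n_pcs", "knn_k", "snn_prune", "umap_neighbors",
            "umap_min_dist", "lower_median", "upper_median", "min_granule",
            "max_search_iter", "clustering", "seed",
        ),
    }

    def config_hash(self, scope: str = "all") -> str:
        """Stable hash used to detect stale intermediate artifacts.

        ``scope`` restricts the hash to the fields an artifact actually
        depends on (``"scoring"`` for score tables, ``"granulate"`` for
        partitions, ``"all"`` for everything).
        """
        d = self.to_dict()
        if scope != "all":
            fields = self._SCOPE_FIELDS[scope]
            d = {k: d[k] for k in fields}
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise InputError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config file {p} is not a key-value mapping")
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if "scores" in raw:
        raw["scores"] = [
            ScoreSpec(**s) if isinstance(s, dict) else ScoreSpec(name=str(s))
            for s in raw["scores"]
        ]
    if "mito_prefixes" in raw:
        raw["mito_prefixes"] = tuple(raw["mito_prefixes"])
    if "ribo_prefixes" in raw:
        raw["ribo_prefixes"] = tuple(raw["ribo_prefixes"])
    return RunConfig(**raw)


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed.

    A single user-facing seed fans out to stage seeds keyed by the stage
    name, so any stage can be re-run in isolation and reproduce the same
    stream it saw inside the full pipeline.
    """
    return (int(base_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)
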