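"""Synthetic scRNA-seq data with a planted stressed subpopulation.

The generator emulates the structure the filtering method targets: a
mixture of cell programs (types), each with its own marker genes, plus a
*stress state* overlaid on cells of every program.  Stressed cells
elevate two designated stress gene sets (standing in for glycolysis and
ER-stress response) and deplete their own program's lineage markers, so
stress is an acute state on top of identity rather than a separate
lineage — stressed progenitors and stressed neurons alike converge on a
shared transcriptional signature.

Counts follow a negative-binomial model: each (program, stressed)
combination has a relative expression profile; a cell's expected counts
are its profile times a log-normal library size; observed counts are
Gamma-Poisson draws with a shared dispersion, reproducing the
overdispersion of UMI data.

Marker sets are disjoint blocks of genes, which keeps ground-truth
checks unambiguous.  Ground-truth labels and GMT fixtures for the
planted sets are emitted alongside the matrix, so the full pipeline is
testable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .matrix_io import CountMatrix, GeneSet, write_10x_mtx, write_gmt

__all__ = ["SynthSpec", "SynthTruth", "SynthBundle", "generate", "default_fixture", "write_fixture"]

GLYCOLYSIS = "GO:0006096"
ER_STRESS = "GO:0034976"
GLIOGENESIS = "GO:0042063"


@dataclass
class SynthSpec:
    """Parameters of the planted-truth simulation.

    Log-fold changes are natural logs: ``stress_lfc = 1.5`` multiplies
    stress-set gene rates by ``e^1.5 ~ 4.5`` in stressed cells.  Library
    sizes are log-normal with a median of ~3,500 UMI per cell, a typical
    10x depth.  ``dispersion`` is the negative-binomial size parameter
    (smaller = more overdispersed).
    """

    n_cells: int = 20_000
    n_genes: int = 2_000
    n_programs: int = 4
    fraction_stressed: float = 0.15
    stress_lfc: float = 1.5
    lineage_depletion_lfc: float = 1.5
    marker_lfc: float = 1.5
    genes_per_stress_set: int = 50
    genes_per_program: int = 50
    libsize_meanlog: float = math.log(3500.0)
    libsize_sdlog: float = 0.35
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_stressed < 1.0:
            raise ParameterError("fraction_stressed must be in [0, 1)")
        if self.n_programs < 2:
            raise ParameterError("n_programs must be >= 2")
        for name in ("stress_lfc", "lineage_depletion_lfc", "marker_lfc",
                     "dispersion", "libsize_sdlog"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        needed = 2 * self.genes_per_stress_set + self.n_programs * self.genes_per_program
        if needed > self.n_genes:
            raise ParameterError(
                f"marker layout needs {needed} genes but n_genes={self.n_genes}"
            )


@dataclass
class SynthTruth:
    stressed: np.ndarray  # per-cell bool
    program: np.ndarray  # per-cell int
    marker_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def stressed_fraction(self) -> float:
        return float(self.stressed.mean())


@dataclass
class SynthBundle:
    counts: CountMatrix
    truth: SynthTruth
    gene_sets: list[GeneSet]
    spec: SynthSpec


def _profiles(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Relative expression profile per (program, stressed) combination.

    Returns an array of shape (n_programs, 2, n_genes) where the second
    axis indexes the stress state, each row summing to 1, plus the
    marker-block layout.
    """
    g = spec.n_genes
    base = rng.gamma(shape=0.4, scale=1.0, size=g) + 1e-4  # heavy-tailed rates
    k = spec.genes_per_stress_set
    m = spec.genes_per_program
    layout = {
        GLYCOLYSIS: np.arange(0, k),
        ER_STRESS: np.arange(k, 2 * k),
    }
    for p in range(spec.n_programs):
        layout[f"program_{p}"] = np.arange(2 * k + p * m, 2 * k + (p + 1) * m)

    prof = np.empty((spec.n_programs, 2, g))
    for p in range(spec.n_programs):
        own = layout[f"program_{p}"]
        healthy = base.copy()
        healthy[own] *= math.exp(spec.marker_lfc)
        stressed = healthy.copy()
        stressed[layout[GLYCOLYSIS]] *= math.exp(spec.stress_lfc)
        stressed[layout[ER_STRESS]] *= math.exp(spec.stress_lfc)
        stressed[own] *= math.exp(-spec.lineage_depletion_lfc)
        prof[p, 0] = healthy / healthy.sum()
        prof[p, 1] = stressed / stressed.sum()
    return prof, layout


def generate(spec: SynthSpec) -> SynthBundle:
    """Draw a synthetic dataset with ground-truth stress labels."""
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    gene_ids = np.array([f"GENE{i:05d}" for i in range(g)], dtype=object)
    cell_ids = np.array([f"CELL{i:06d}" for i in range(n)], dtype=object)

    prof, layout = _profiles(spec, rng)
    program = rng.integers(spec.n_programs, size=n)
    n_stressed = round(spec.fraction_stressed * n)
    stressed = np.zeros(n, dtype=bool)
    stressed[rng.choice(n, size=n_stressed, replace=False)] = True
    libsize = rng.lognormal(spec.libsize_meanlog, spec.libsize_sdlog, size=n)

    theta = spec.dispersion
    blocks = []
    chunk = 2048
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        mu = prof[program[start:stop], stressed[start:stop].astype(int)] * libsize[
            start:stop, None
        ]
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
    counts = sp.vstack(blocks, format="csr")

    marker_sets = {name: gene_ids[idx].tolist() for name, idx in layout.items()}
    gene_sets = [
        GeneSet(GLYCOLYSIS, marker_sets[GLYCOLYSIS], "positive", "glycolytic process"),
        GeneSet(ER_STRESS, marker_sets[ER_STRESS],
                "positive", "response to endoplasmic reticulum stress"),
        # program 0 plays the glia lineage: its markers double as the
        # gliogenesis veto set
        GeneSet(GLIOGENESIS, marker_sets["program_0"], "negative", "gliogenesis"),
    ]
    truth = SynthTruth(stressed=stressed, program=program, marker_sets=marker_sets)
    return SynthBundle(
        counts=CountMatrix(counts, cell_ids, gene_ids),
        truth=truth,
        gene_sets=gene_sets,
        spec=spec,
    )


def default_fixture(seed: int = 1) -> SynthBundle:
    """The canonical test dataset: 20,000 cells, 2,000 genes, 4 programs,
    15% stressed cells, stress log-fold change 1.5."""
    return generate(SynthSpec(seed=seed))


def write_fixture(bundle: SynthBundle, out_dir) -> None:
    """Materialize a bundle as a 10x MTX directory + truth TSV + GMT."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_10x_mtx(bundle.counts, out / "matrix")
    pd.DataFrame(
        {
            "cell_id": bundle.counts.cell_ids,
            "program": bundle.truth.program,
            "is_stressed": bundle.truth.stressed,
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
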