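"""Readers and writers for the standard formats the tool touches.

Supported on-disk formats:

* 10x Genomics MTX directories (MatrixMarket matrix plus barcode and
  feature tables, plain or gzipped, v2 ``genes.tsv`` or v3
  ``features.tsv`` naming),
* GMT gene-set files,
* TSV tables for stress calls and granule partitions.

Gene symbols are the join key throughout: gene sets are symbol lists, so
the features table's symbol column (column 2 when present) becomes
``gene_ids`` and Ensembl-ID columns are ignored.  Duplicate symbols are
made unique by suffixing (``ACTB``, ``ACTB.1``, ...).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError

__all__ = [
    "CountMatrix",
    "GeneSet",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gmt",
    "write_gmt",
    "write_calls",
    "read_calls",
    "write_partition_tsv",
    "read_partition_tsv",
]


def _dedupe(names: Iterable[str]) -> np.ndarray:
    """Make strings unique by appending ``.1``, ``.2``, ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return np.asarray(out, dtype=object)


@dataclass
class CountMatrix:
    """Sparse cell-by-gene UMI count matrix.

    ``counts`` is a CSR matrix of non-negative integers with one row per
    cell and one column per gene; ``cell_ids`` and ``gene_ids`` are
    unique string identifiers for the rows and columns.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise FormatError(
                f"count matrix is {n}x{g} but {len(self.cell_ids)} cell ids "
                f"and {len(self.gene_ids)} gene ids were given"
            )
        if len(set(self.cell_ids)) != n:
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise FormatError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.counts.nnz and not np.all(np.isfinite(self.counts.data)):
            raise FormatError("non-finite counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.counts[mask], self.cell_ids[mask], self.gene_ids)


@dataclass
class GeneSet:
    """A named list of gene symbols used for pathway scoring.

    ``direction`` controls how the score's threshold is used downstream:
    ``"positive"`` sets select stressed granules (e.g. glycolysis,
    ER-stress); ``"negative"`` sets veto the call, protecting cell types
    with a high native score (e.g. gliogenesis).
    """

    name: str
    genes: list[str]
    direction: str = "positive"
    description: str = ""
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            # keep first occurrence, preserve order
            seen = set()
            self.genes = [g for g in self.genes if not (g in seen or seen.add(g))]
        if self.direction not in ("positive", "negative"):
            raise FormatError(
                f"gene set {self.name!r}: direction must be positive/negative"
            )


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / (stem + suffix)
            if p.exists():
                return p
    raise InputError(
        f"none of {list(stems)} (or .gz) found in {directory}"
    )


def read_10x_mtx(directory_path: str | os.PathLike) -> CountMatrix:
    """Read a 10x-convention MTX directory into a :class:`CountMatrix`.

    Accepts both the v2 layout (``matrix.mtx``, ``barcodes.tsv``,
    ``genes.tsv``) and the v3 layout (gzipped, ``features.tsv.gz``).
    The on-disk genes-in-rows orientation is transposed to cells x genes.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    mtx = _find(directory, ["matrix.mtx"])
    barcodes = _find(directory, ["barcodes.tsv"])
    features = _find(directory, ["features.tsv", "genes.tsv"])

    try:
        with _open_maybe_gz(mtx, "rb") as fh:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
    except Exception as exc:  # malformed MatrixMarket header/body
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    counts = sp.csr_matrix(mat.T)  # genes x cells on disk

    with _open_maybe_gz(barcodes) as fh:
        cell_ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(features) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # column 2 is the symbol in both 10x dialects; 1-column tables are
    # already symbol lists
    symbols = [r[1] if len(r) > 1 else r[0] for r in rows]

    if counts.shape[0] != len(cell_ids) or counts.shape[1] != len(symbols):
        raise FormatError(
            f"matrix is {counts.shape[1]} genes x {counts.shape[0]} cells but "
            f"{len(symbols)} features and {len(cell_ids)} barcodes were read"
        )
    return CountMatrix(counts, np.asarray(cell_ids, dtype=object), _dedupe(symbols))


def write_10x_mtx(m: CountMatrix, directory_path: str | os.PathLike, *, gzipped: bool = False) -> None:
    """Write a :class:`CountMatrix` as a 10x-convention MTX directory."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(m.counts.T), field="integer")
    with _open_maybe_gz(directory / f"matrix.mtx{suffix}", "wb") as fh:
        fh.write(buf.getvalue())
    with _open_maybe_gz(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(map(str, m.cell_ids)) + "\n")
    with _open_maybe_gz(directory / f"features.tsv{suffix}", "wt") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name TAB description TAB genes...``."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"GMT file not found: {p}")
    sets = []
    with _open_maybe_gz(p) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{p}:{i}: GMT line has {len(fields)} fields (< 3)")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=genes, description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or gs.name, *gs.genes]) + "\n")


# -- stress-call table --------------------------------------------------

def write_calls(calls, path: str | os.PathLike) -> None:
    """Write a :class:`~granufilt.stresscall.StressCall` as TSV.

    Columns: ``cell_id``, ``granule_id``, one column per score (granule
    value in granular mode, cell value in single-cell mode), then
    ``is_stressed``.  Rows are sorted by cell id for stable diffs.
    """
    df = calls.cell_table.copy()
    df = df.sort_index()
    df.index.name = "cell_id"
    try:
        df.to_csv(path, sep="\t")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"calls table not found: {p}")
    df = pd.read_csv(p, sep="\t", index_col="cell_id")
    df["is_stressed"] = df["is_stressed"].astype(bool)
    return df


def write_partition_tsv(partition, path: str | os.PathLike) -> None:
    """Export a granule partition as a two-column TSV (cell_id, granule_id)."""
    pd.DataFrame(
        {"cell_id": partition.cell_ids, "granule_id": partition.labels}
    ).to_csv(path, sep="\t", index=False)


def read_partition_tsv(path: str | os.PathLike) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise InputError(f"partition table not found: {p}")
    df = pd.read_csv(p, sep="\t")
    if list(df.columns[:2]) != ["cell_id", "granule_id"]:
        raise FormatError(f"{p}: expected columns cell_id, granule_id")
    return df
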