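# Methods

## The problem

3D tissue cultures such as brain organoids develop diffusion-limited
hypoxia: cells far from the surface experience metabolic stress, switch
on glycolysis and the unfolded-protein/ER-stress response, and partially
shut down lineage-specific transcription. In single-cell RNA-seq these
stressed cells form an artifactual subpopulation not seen in primary
tissue, which distorts clustering, trajectory inference and comparisons
to in vivo references. `granufilt` identifies and removes that
subpopulation from a cell-by-gene UMI count matrix using only gene-set
activity scores — no manual cluster annotation.

## Pipeline model

The method rests on four components, applied after standard QC and
CP10K log-normalization (`log1p(10,000 · count / cell total)`):

### 1. Binned-control module scores

For a gene set *G* the per-cell score is

    score(c) = mean_{g in G} x_cg − mean_{g in C} x_cg

where *x* is log-normalized expression and *C* is a control pool
matched to *G* by expression level: all genes are ranked by mean
expression over cells and cut into `n_bins = 25` equal-frequency bins;
for each target gene, `n_ctrl = 100` genes are drawn uniformly from its
bin (without replacement when the bin is large enough, with replacement
otherwise), and the pool is the union of the draws. Matching controls
by expression level cancels cell-to-cell differences in depth and
quality, which dominate the variability of raw set means. Members of
*G* are never eligible as controls: allowing them would subtract part
of the signal being measured (with a single bin, a planted offset δ on
the target genes is then recovered exactly as a score of δ).

Binning is rank-based with ties broken by gene symbol, and control
sampling iterates target genes in set order, so a fixed seed gives
bit-identical scores. Scores are shift-invariant (adding a constant to
the whole matrix changes nothing) and equivariant under cell
permutations.

### 2. Granules by resolution-searched clustering

Per-cell scores are noisy because gene detection is noisy. Cells are
therefore grouped into *granules* — clusters of ~100–200 cells from
Louvain modularity clustering of the shared-nearest-neighbor graph
(Jaccard weights of k=20 PCA-space neighborhoods, pruned below 1/15,
PCA on 50 components of the 2,000 most variable genes, z-scaled) — and
scores are averaged per granule. The resolution that yields the target
median size is dataset-dependent, so it is searched automatically:
starting at resolution 1, double (too-large granules) or halve
(too-small), then bisect the bracketing pair in log space; accept the
first resolution whose median granule size lies in the closed band
`[lower_median, upper_median] = [100, 200]`; fail loudly after 30
clusterings. Smaller datasets warrant smaller bands (e.g. 75–150), set
via `RunConfig`.

Granules under `min_granule = 30` cells are too small for a stable
mean; every cell of such a granule is reassigned to the granule (among
those already ≥ 30 cells) with the nearest centroid in 3-D UMAP space,
centroids frozen before any transfer. A single frozen-centroid pass
guarantees termination and the post-condition (all sizes ≥ 30) without
cascading; iterating to a fixed point was considered and rejected as
it can oscillate and never changes more than a few boundary cells on
realistic data.

### 3. Automatic thresholds from a contaminated Gaussian

Granule scores are means of ≥ 30 (typically ≥ 100) cells, so by the
central limit theorem the scores of *non-stressed* granules are
approximately normal. Assuming stressed granules (i) score higher and
(ii) are the minority, they contaminate only the upper tail. The
Gaussian is therefore fitted one-sidedly:

    m = median(granule scores)
    s = sqrt( mean_{x < m} (x − m)² )      (0 if no score is below m)
    t = m + z_q · s,  z_q = Φ⁻¹(q),  q = 0.99

The location comes from the median (robust to the upper-tail
contamination), the scale only from scores strictly below the median —
a half-sample RMS, the faithful estimator of the fitted normal's σ
under the symmetric-null assumption. On clean standard-normal scores,
`s → 1` and `t → z₀.₉₉`, leaving 99% of granules below the cutoff, so
`q` directly controls the false-calling budget. The RMS uses the
population divisor (the count of lower-half scores); with distinct
values that is ⌊n/2⌋.

### 4. Combining scores into calls

A granule is called stressed iff **any** positive score (defaults:
glycolytic process GO:0006096, response to ER stress GO:0034976)
exceeds its threshold **and no** negative score (default: gliogenesis
GO:0042063) exceeds its own. Negative scores veto the call to protect
cell types with high native pathway activity — glia are natively
glycolytic, retinal ganglion cells likewise, so a user can supply any
marker list as a negative set. Inequalities are strict: a granule
exactly at the threshold is non-stressed. The per-granule verdict is
broadcast to member cells; adding a negative set can only shrink the
stressed set, and the threshold is monotone in `q` and affine
equivariant in the scores.

A single-cell mode applies the same fit and combination to raw
per-cell scores (no granule averaging). It exists for comparison: at a
quantile matched to produce the same number of calls, its specificity
is no better than the granular mode's, because cell-level score noise
leaks individual cells across the threshold in both directions.

Thresholds can be overridden manually (`--threshold NAME=VALUE`, or
`manual_thresholds` in the config) after inspecting the
`threshold-report` histogram; the automatic values are the tested
default.

## Synthetic data

`granufilt.synthsim` generates negative-binomial counts with planted
ground truth: `n_programs` cell types with disjoint 50-gene marker
blocks (elevated e^1.5-fold), two disjoint 50-gene stress sets, and a
stress state overlaid on a fraction of cells of *every* program —
stressed cells multiply stress-set rates by `e^stress_lfc` and their
own program's markers by `e^−lineage_depletion_lfc`. Library sizes are
log-normal (median ~3,500 UMI, σ_log = 0.35); counts are Gamma-Poisson
with size 10. Defaults: 20,000 cells × 2,000 genes, 4 programs, 15%
stressed, `stress_lfc = 1.5`.

Choices worth stating:

- **Stress as a state, not a lineage.** Stressed cells are drawn from
  all programs, so "stressed progenitors" and "stressed neurons" both
  exist and converge on a shared signature — the structure the
  granular veto logic must handle (program 0's markers double as the
  gliogenesis veto set).
- **`lineage_depletion_lfc = 1.5`**, equal to the marker elevation, so
  a stressed cell's lineage markers return to the background rate;
  stress suppresses, but does not invert, identity expression.
- **Dispersion.** NB size 10 gives variance ≈ μ + μ²/10, a typical
  UMI-level overdispersion; Poisson data would understate the score
  noise the granule averaging exists to absorb.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, continuous differentiation trajectories, partial/graded
stress, and gene-gene correlation beyond the program blocks. Passing
the recovery tests therefore shows the machinery is correct and
calibrated under the stated model, not that real organoid data will
separate as cleanly; on real data the thresholds remain data-driven
but the stressed/non-stressed margin is narrower and threshold
inspection (`threshold-report`) is worth the minute it takes.

## Numerical and design notes

- **Problem sizes.** The bundled full-scale dataset is 20,000 cells ×
  2,000 genes (one run ≈ 80 s on a laptop core, UMAP included); unit
  tests use 20–4,000 cells. Effect-size sweeps skip UMAP/reassignment,
  which calling does not require when no granule is under-sized.
- **Determinism.** One global seed fans out to per-stage seeds
  (XOR with a CRC32 of the stage name), so `score`, `granulate` and
  `run` reproduce each other's artifacts exactly. Louvain runs through
  igraph's RNG (seeded per call); UMAP uses a fixed `random_state`.
  Repeated runs on the same machine are byte-identical.
- **Degenerate inputs.** All-equal granule scores give `s = 0`,
  `t = m`, and (strict inequality) zero calls — a fully null dataset
  is left untouched. Cells with zero counts normalize to zero with a
  warning. QC refuses to empty a dataset; filtering refuses to remove
  every cell; the resolution search reports every attempted resolution
  when it fails to bracket the band.
- **Ties.** HVG ranking and expression binning break ties by gene
  symbol; the resolution search accepts band edges (closed interval).
- **Duplicate gene symbols** from 10x features tables are suffixed
  (`ACTB`, `ACTB.1`) at read time, since symbols are the join key
  between matrices and gene sets.
- **Known limitations.** The threshold model assumes non-stressed
  granule scores share one unimodal distribution;
  strongly multi-modal score distributions across cell types inflate
  the lower-tail scale or, worse, put a whole cell type over the
  threshold — that is exactly what negative sets are for, and why the
  report prints the per-score histograms. The Jaccard SNN graph is
  built from exact kNN; for datasets ≫ 10⁵ cells an approximate-NN
  backend would be the first thing to add.
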