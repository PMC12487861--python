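# Methods

## Scope and data model

The package analyses one multi-FOV imaging spatial-transcriptomics run held
in a `SpatialDataset`: per-cell records (unique id, FOV, global x/y in
micrometres, optional cell-type label) plus a genes × cells matrix of raw
non-negative integer counts and a per-FOV global tile origin. Flat files are
read and written in the vendor dialect (`exprMat_file.csv.gz`,
`fov_positions_file.csv.gz`, `metadata_file.csv.gz`, optional
`polygons.csv.gz` / `tx_file.csv.gz`, all gzip CSV with `fov`/`cell_ID` key
columns). Polygon and transcript-location tables are carried as opaque
extras; no analysis consumes them.

**Coordinates.** Global position = FOV origin + local centroid, Cartesian,
y increasing upward, multiplied by `coordinate_scale` (µm per raw unit,
default 1.0 — i.e. "the export is already in µm"). The 20 µm proximity
threshold is only meaningful in µm, so the scale is an explicit knob rather
than a guess; exports in pixels must set it. Cell ids are made globally
unique as `<fov>_<cell_ID>`. Flat-file writes pin the gzip mtime to zero,
so identical datasets produce byte-identical files.

## Quality control

* **scRNA-Seq-style filter** (`filter_scrna_cells`): a cell is removed iff
  total transcripts < 500 OR detected genes < 100 OR mitochondrial fraction
  > 0.10. All three comparisons are strict, so boundary cells (exactly 500
  transcripts, 100 genes, 10% mito) are retained. A zero-count cell has an
  undefined mitochondrial fraction; it is removed under the transcript rule
  with the fraction treated as zero, never as a division error.
  Mitochondrial genes are matched by a caller-supplied predicate (default:
  `MT-` name prefix). The report attributes each removed cell to *every*
  rule it violates, so rule counts can exceed the number of removed cells.
* **Spatial-panel filter** (`filter_cosmx_cells`): control probes (names
  starting with `Neg` or `System`, configurable) are removed first because
  they are not biological signal; cell totals are then recomputed on the
  biological panel and cells with < 20 counts (strict) are dropped. The
  order is fixed and visible in the report (`n_genes_removed` vs cell
  rules). Both filters are idempotent and per-cell independent.

## Gating

A gating rule is a conjunction: a cell carries the subset label iff its raw
count ≥ `positivity_min_count` (default 1) for every required marker. The
default of "at least one transcript" is the minimal reading of gating on
expression; it is configurable for robustness analyses, and gating operates
on raw counts (panel counts are not normalised before thresholding). Rules
are independent gates — a cell satisfying several rules belongs to each
subset; downstream analyses treat multi-gated cells as members of every
subset independently. Marker names are normalised (upper case, hyphens and
dots stripped) before matching, reconciling spellings such as `IL-17F` vs
`IL17F`. Built-in rules: IL36G_KC `{IL36G}`, Treg `{CD4, FOXP3, IL2RA}`,
Th17 `{CD4, IL17A, RORC}`, regTh17 `{IL17F, IL26, FOXP3}`, NKT
`{CD8A, NKG7, KLRD1}`.

## Neighborhood enrichment

Per FOV, each cell's `min(k, n_fov − 1)` nearest neighbors by Euclidean
distance are found, self excluded. Neighbor search is exact (blocked
all-pairs distances); ties at the k-th distance are broken by ascending
cell id, which makes results deterministic and invariant under permutation
of input order — tree-based searches do not guarantee a tie order. The
exact search is quadratic per FOV and comfortable up to roughly 10⁴ cells
per tile. FOVs smaller than k + 1 cells contribute all their n − 1
neighbors rather than being discarded, which would bias composition; a
singleton FOV yields an empty neighbor set with a logged warning.

Aggregation: (i) cell types with fewer than `min_cells_per_type` (default
20) total cells across all FOVs are excluded from both axes; (ii)
`raw[s, r]` sums neighbor counts of receiver type r over all focal cells of
sender type s; (iii) each column is divided by `N_r`, the total number of
cells of receiver type r in the analysed dataset — the pool of potential
neighbors — correcting for abundance; (iv) rows are rescaled to sum to
100. The abundance correction followed by row rescaling is the only
normalisation under which rows of a percentage matrix sum to 100 while
still accounting for receiver frequency; a flag disables step (iii) to
emit raw composition percentages instead, and both variants are exportable.
Unlabeled neighbors are dropped with a warning by default (configurable to
an error).

**Permutation null.** `permutation_pvalue` shuffles labels across all
labelled cells, keeping the spatial graph fixed, recomputes one
sender → receiver percentage per shuffle, and reports the one-sided
empirical p-value `(1 + #{null ≥ observed}) / (1 + n_permutations)`.

**Choosing k.** The default k = 150 matches dense full-tissue runs. The
neighborhood radius implied by k grows as √(k / density); on the synthetic
desk-scale datasets (≈ 360 cells per 500 × 500 µm tile) k = 150 spans most
of a tile and washes out 15 µm niches, so the niche-recovery analyses and
examples use k = 10 (implied radius ≈ 50 µm, commensurate with the planted
geometry). The CLI accepts a list of k values and writes one matrix per k.

## Proximity analysis

For each immune cell the distance to the nearest target cell (default the
IL36G_KC gate) is computed. Scope defaults to within-FOV, consistent with
the neighborhood statistic — stitched distances across non-adjacent tiles
are physically meaningless; global scope is a flag. A query in a tile
without targets gets a missing distance (warned, excluded downstream). A
query that is itself a target is matched against the remaining targets
only. Strata: Near iff distance < 20 µm (strict); exactly 20 µm is Far.

Comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test on the
two subsets' distance vectors: exact enumeration when both groups have ≤ 20
observations and the pooled sample is tie-free (exact p-values are not
defined under ties), tie-corrected normal approximation otherwise. All
subset pairs are tested; a Fisher exact test on the 2 × 2 Near/Far counts
is emitted alongside as a sensitivity output, since "compare subsets" can
reasonably mean either quantity. No multiplicity correction is applied by
default; a flag adds Benjamini–Hochberg.

## Expression summaries

For each panel gene (default: CD3E, CD4, CTLA4, FOXP3, IL17A, IL17F, IL26,
IL36G) and each cell type: mean, median and total raw count per cell, plus
the cell count. Raw counts are summarised deliberately — the medians of
sparse panel counts are only interpretable on the integer scale.

## Synthetic generator

`generate_spatial` emulates the statistical shape of an inflamed-skin run:

* **Geometry.** Per tile (default two 500 × 500 µm FOVs), each type's cell
  count is Poisson with the configured expectation (defaults: 60 IL36G_KC,
  40 each of Treg/Th17/regTh17/NKT, 90 keratinocytes, 70 fibroblasts —
  immune-rich lesional-biopsy-like proportions at a plausible ~1.5 × 10⁻³
  cells/µm²). Positions are uniform; a Thomas-style clustered anchor
  process is available to stress the enrichment statistic. A niche spec
  `(attracted, anchor, radius, fraction)` places the given fraction of the
  attracted type uniformly inside a disc around a random same-FOV anchor
  (default: regTh17 around IL36G_KC, radius 15 µm, fraction 0.8),
  rejection-sampled back into the tile. A density guard errors when the
  expected count exceeds tile capacity at a declared 2 µm minimum spacing
  (a sanity bound, not a hard-core process).
* **Counts.** Negative binomial per gene, dispersion 10 (mildly
  overdispersed Poisson, the standard choice for transcript counts), with
  type-specific means: 6 for a type's own gate markers, 0.005 background.
  At these settings a planted cell passes its own 3-marker gate with
  probability ≈ 0.97 and off-type cells pass any gate with probability
  ≤ 0.05, so planted labels and gating agree at the 95% level. Ten
  housekeeping genes (mean 8) keep totals above the 20-count QC floor, and
  10 negative + 5 system control probes (mean 0.05) exercise the probe
  filter. A few biological touches (CD3E in T cells, CTLA4 in Treg/regTh17,
  KRT14/COL1A1 in structural types) make the expression summary
  non-trivial.
* **Determinism.** Identical config + seed ⇒ bit-identical dataset and
  byte-identical flat files.

`generate_count_matrix` builds the scRNA-Seq QC fixture: ordinary cells
(~600 transcripts over ~250 genes, ~2% mito) plus cells planted to violate
exactly one rule each — low-transcript (~300 total, ≥ 100 genes), low-gene
(~900 total on ≤ 70 genes), high-mito (~20%) — and optional deterministic
boundary cells sitting exactly on every threshold. Violations are separated
from the thresholds by many standard deviations, so the planted sets are
removed exactly with overwhelming probability at any seed.

**What the generator does not emulate:** real segmentation errors, the
1,000-plex panel size, spatially varying density, tissue morphology,
batch/FOV effects, or ambient contamination. Passing tests therefore
demonstrate the correctness and calibration of the statistics, not
robustness to those artefacts.

## Problem sizes

The shipped analyses run at desk scale by choice: ~700-cell two-FOV
datasets, 99 label permutations, 10 seeds for niche recovery, 50 replicates
(300 pairwise p-values) for null calibration, and 20 random ≤ 500-cell
instances for the brute-force equivalence check. These sizes give stable
verdicts (permutation p floor 0.01; KS on 300 p-values) while keeping the
full suite under a minute.

## Known limitations

* The enrichment matrix's receiver-abundance normalisation assumes the
  label set is fixed across FOVs; types concentrated in a few tiles are
  normalised by their global abundance.
* Exact k-NN is quadratic per FOV; very large tiles (≫ 10⁴ cells) would
  need a tree-based path with explicit tie handling.
* Near/Far proportions are sensitive to the coordinate scale; nothing can
  validate the µm calibration of an export from within the data.
* The Wilcoxon "exact" branch switches to the asymptotic approximation in
  the presence of any tie, including at small n.
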