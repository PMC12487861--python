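# spatialniche

Spatial-niche analysis for imaging-based spatial transcriptomics (CosMx-style
flat-file exports): marker-rule cell gating, per-FOV k-nearest-neighbor
neighborhood enrichment, nearest-target proximity stratification, the
associated quality-control filters, and per-cell-type expression summaries.

It is aimed at analysts asking *which cell types sit next to which* in tissue
— the motivating case being pustular skin inflammation, where a hybrid
regulatory/Th17 T-cell population (regTh17, gated `IL17F+ IL26+ FOXP3+`) is
suspected to occupy niches around IL-36G-expressing keratinocytes. Because
clinical spatial runs are rarely shareable, the package ships a synthetic
generator that plants exactly this kind of niche structure, so every stage is
testable end to end without patient data.

## The statistics at the core

**Neighborhood enrichment.** Within each field of view (FOV), each cell's
*k* nearest neighbors by Euclidean distance are found (default *k* = 150,
self excluded, ties broken by cell id). Neighbor cell-type counts are
aggregated across FOVs into a sender × receiver matrix. With `N_r` the total
number of cells of receiver type *r* and `raw[s, r]` the summed neighbor
counts,

```
norm[s, r] = raw[s, r] / N_r          (abundance correction)
E[s, r]    = 100 · norm[s, r] / Σ_r' norm[s, r']
```

so every retained sender row sums to 100%. Cell types with fewer than 20
total cells are excluded from both axes. A label-permutation null
(`permutation_pvalue`) tests whether a particular sender → receiver entry
exceeds chance.

**Proximity stratification.** For each immune cell the Euclidean distance to
the nearest IL-36G⁺ keratinocyte is computed (within-FOV scope by default)
and stratified as **Near** (< 20 µm, strict) or **Far** (≥ 20 µm). Subset
distance distributions are compared with the two-sided Wilcoxon rank-sum
test (exact enumeration for tie-free groups of ≤ 20, tie-corrected normal
approximation otherwise).

**QC filters.** scRNA-Seq style: drop cells with < 500 transcripts, < 100
detected genes, or > 10% mitochondrial counts (all strict; boundary cells
pass). Spatial-panel style: drop control probes (`Neg*`, `System*`) first,
then cells with < 20 remaining counts.

## Worked example

```python
import spatialniche as sn

# synthetic run: 2 FOVs, 7 cell types, regTh17 planted within 15 µm of
# IL-36G+ keratinocyte anchors (fraction 0.8)
ds, truth, _ = sn.generate_spatial(sn.SimConfig(seed=3))

matrix, _ = sn.run_enrichment(ds, truth.to_dict(),
                              sn.NeighborhoodParams(k=10, min_cells_per_type=20))
print(matrix.round(1))
```

```
              Fibroblast  IL36G_KC  Keratinocyte   NKT  Th17  Treg  regTh17
sender
Fibroblast          13.8      15.2          13.9  13.2  13.8  16.1     14.1
IL36G_KC            14.9       9.7          14.4  15.7  13.5  14.9     16.9
Keratinocyte        13.5      15.0          14.2  14.4  12.8  14.8     15.3
NKT                 14.0      15.8          15.8  16.2  14.3  11.9     12.0
Th17                14.1      14.5          14.2  15.8  11.3  15.4     14.7
Treg                15.6      14.4          14.7  12.1  14.9  15.4     12.8
regTh17             14.4      16.9          13.8  12.2  15.1  14.0     13.6
```

The regTh17 row peaks in the IL36G_KC column (16.9% vs a label-permutation
null mean of 14.2%, empirical p = 0.02 over 99 permutations) — the planted
niche is recovered. The proximity side of the same run:

```python
gating = sn.gate_cells(ds)                    # marker-rule gating
table = sn.proximity_table(ds, gating)        # nearest IL-36G+ KC per immune cell
print(sn.subset_proportions(table))
```

```
    subset  prop_near  prop_far   n
0      NKT      0.246     0.754  57
1     Th17      0.233     0.767  73
2     Treg      0.390     0.610  82
3  regTh17      0.810     0.190  84
```

regTh17 has by far the highest Near (< 20 µm) proportion, as planted.

The same pipeline runs from the shell:

```
spatialniche run-all --seed 3 --out results/demo
```

which writes the QC report, gating table, enrichment matrix, proximity
tables and expression summary plus a JSON run manifest. Real flat-file
exports are analysed with the `qc`, `gate`, `enrich`, `proximity` and
`summarize` subcommands pointed at the export directory.

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
conventions and the limits of what the synthetic generator emulates.
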