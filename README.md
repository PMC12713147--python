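# gcniche

Spatial positioning analysis for the germinal-center (GC) niche in
lymphoid tissue, built for imaging-based spatial transcriptomics of
tonsil. The package answers a concrete question: **which genes, when
expressed by a T follicular helper (Tfh) cell, actually predict that the
cell sits inside a germinal center?** Classic GC-associated markers
(*BCL6*-like programs) turn out to be poor positional predictors —
a substantial share of the Tfh expressing them sit outside GCs — while
tightly GC-restricted activation features rank at the very top.

It is intended for computational immunologists working with segmented-cell
spatial data (cell centroids, type labels, probe-panel counts), optionally
paired with a dissociated single-cell reference.

## What it computes

1. **Cellular neighborhoods (CNs).** Each cell's neighborhood vector is
   the cell-type composition of its *k* nearest neighbors (self included,
   default *k* = 20, within sample). K-means over these vectors (default
   10 CNs, joint across samples) yields tissue compartments, annotated by
   declarative composition rules (GC LZ, GC DZ, mantle, T zone,
   epithelium).
2. **Merged GC mask.** GC-annotated CNs are rasterized (20 µm bins),
   morphologically closed, and hole-filled by border flood-fill, so CNs
   interspersed *inside* GCs count as GC. A cell is "in GC" iff its bin is.
3. **Positional PPV ranking.** Each gene's positive predictive value for
   GC positioning is

   PPV(g) = #{Tfh positive for g inside the GC mask} / #{Tfh positive for g},

   with positivity at ≥ 1 raw count. Included genes (≥ 20 positive Tfh)
   are ranked by PPV; percentile = 100·(1 − (rank − 1)/n), so rank 25 of
   5,101 is the 99.5th percentile.
4. **Contrasts.** Two-sided Wilcoxon rank-sum tests per gene
   (tie/continuity-corrected normal approximation; exact for tiny tie-free
   groups) with Bonferroni control; log₂FC on library-size-normalized
   means with pseudocount ε.
5. **Three-way specificity.** log₂FC of (i) Tfh in-GC vs out, (ii) Tfh vs
   other cells in-GC, (iii) reference Tfh vs other lineages — genes driven
   by spillover from GC B cells are positive in (i) but *negative* in
   (iii), separating contamination from genuine Tfh expression.
6. **Distance decay.** Nadaraya–Watson Gaussian-kernel curves of Tfh
   expression vs distance to the nearest LZ GC B cell.
7. **Meta-ranking and concordance.** Fisher's method
   (X² = −2(ln p₁ + ln p₂), 4 df) combines RNA and chromatin gene-activity
   p-values; lowest-meta-p genes are ranked by mean log₂FC. Adjusted
   mutual information (arithmetic-mean normalization, hypergeometric-model
   expectation) compares clusterings.

Because public deposits of such data are not bundled, the package ships a
**synthetic tonsil generator** with full ground truth: follicles with
LZ/DZ cores and mantle rings in a T-cell zone with an epithelial band,
region-conditioned cell types, negative-binomial gene programs in seven
classes with graded GC restriction, and cell-to-cell contamination
(transcript diffusion, segmentation swaps, vertical overlap). Every
downstream claim is tested against what was planted.

## Worked example

```sh
gcniche simulate demo --seed 3 --small
gcniche run-all demo/cells.tsv demo/counts.mtx demo/genes.txt demo/cells.txt \
    demo/out --seed 3 --with-reference
```

prints (abridged):

```
wrote 5892 cells, 200 genes to demo
top included genes by GC PPV:
    gene      ppv  rank  percentile
GCTFH002 0.954545     1       100.0
GCTFH003 0.942675     2        99.5
GCTFH001 0.930818     3        99.0
GCTFH004 0.927632     4        98.4
  GCB012 0.911765     5        97.9
```

Reading: of the Tfh positive for `GCTFH002` (a planted GC-Tfh-restricted
gene), 95.5% lie inside the recovered GC mask — rank 1 of all included
genes. The four planted GC-Tfh-restricted genes occupy the top four
ranks; the first genes to follow are GC-B-restricted (`GCB012`): their
transcripts reach Tfh only by spillover inside GCs, which is why the
three-way contrast (written to `demo/out/three_way_specificity.tsv`)
shows them GC-enriched spatially yet Tfh-depleted in the dissociated
reference. The same analysis is available as a library:

```python
from gcniche import AnalysisConfig, TissueConfig, generate_tissue, run_pipeline

tissue = generate_tissue(TissueConfig(seed=1))          # ~30k cells, 8 follicles
result = run_pipeline(AnalysisConfig(seed=1), tissue.cells, tissue.counts)
print(result.specificity.head())
```

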