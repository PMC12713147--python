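# Methods

## The analysis model

The pipeline treats a segmented-cell spatial dataset as a marked point
pattern: cell centroids (µm, image convention) with a level-1 type label
and a sparse probe-count vector per cell. Three assumptions drive the
design:

- **Tissue compartments are compositional.** A germinal center is not a
  property of single cells but of local type composition, so compartments
  are inferred from k-nearest-neighbor composition vectors, not from any
  single marker.
- **Counts are contaminated.** Imaging-based assays misassign transcripts
  between adjacent cells (free diffusion, imperfect segmentation, cells
  stacked in z). Any positional statistic computed from raw counts will
  partially reflect a cell's *neighbors*. The three-way contrast is the
  instrument for separating that spillover from genuine expression: a
  gene truly expressed by Tfh is enriched in Tfh in a dissociated
  reference too, whereas a spillover gene is depleted there.
- **Positional specificity is a predictive-value question.** The useful
  quantity for a marker of GC residence is P(in GC | cell positive), not
  a fold change — hence the PPV ranking.

## Pipeline parameters (AnalysisConfig)

| parameter | default | meaning |
|---|---|---|
| `knn_k` | 20 | neighborhood window, self included; ~23 µm radius at tonsil densities — small enough to keep LZ and DZ distinct, large enough to smooth single-cell noise |
| `n_neighborhoods` | 10 | number of CNs resolved by k-means (k-means++, 10 restarts, seeded) |
| `bin_um` | 20.0 | GC-mask raster bin; about one cell diameter |
| `closing_radius_bins` | 2 | binary-closing disk radius (40 µm): bridges inter-cell gaps without merging adjacent follicles |
| `positivity_threshold` | 1 | raw counts for a positive call; probe-panel counts at this depth are near-binary |
| `min_pos_tfh` | 20 | positive Tfh needed for ranking inclusion; excludes degenerate few-cell PPVs |
| `pseudocount` | 1e-9 | ε in log₂((m₁+ε)/(m₂+ε)) |
| `mt_method` | bonferroni | `fdr_bh` available for exploratory use |
| `bandwidth_um` | 25.0 | Gaussian bandwidth of the decay smoother; grid 0–300 µm in 5 µm steps |

CN annotation is rule-based (fraction/enrichment thresholds per type).
The default rules are written to be *mutually exclusive on the whole
composition simplex* (property-tested), so the ambiguity error can only
be triggered by user-supplied rules. CNs matching no rule become
"Other"; when such a CN lies inside a GC it is recovered by hole-filling,
which is exactly the role of that step.

## Statistical choices

- **Rank-sum test.** Normal approximation with tie and continuity
  corrections (the regime of real group sizes, thousands of cells). For
  tiny tie-free groups (both ≤ 8) the exact null distribution is used
  instead; the asymptotic p can differ from the exact one by more than
  0.03 at n = 3 + 3, which is material when a test is the object under
  study rather than a screening device.
- **Fold changes** are computed on library-size-normalized means (median
  total as target). Normalization is compositional: strongly expressed
  programs in one group depress the normalized means of all other genes
  in that group. Tests of "identical planted means ⇒ no signal"
  therefore run on raw means.
- **Fisher's method** for the cross-modality meta p-value, with
  Stouffer-style alternatives deliberately out of scope; the meta log₂FC
  is the unweighted mean of the two modality fold changes. Zero
  p-values are clamped to the smallest positive float with a warning.
- **AMI** uses the arithmetic-mean entropy normalization and the
  hypergeometric (permutation) expectation of MI, computed from the
  contingency table with log-gamma arithmetic; a degenerate zero
  denominator returns 0. The implementation is cross-checked in the test
  suite against scikit-learn's independent implementation.
- **Percentile convention** 100·(1 − (rank − 1)/n), reported to one
  decimal: rank 1 → 100.0, rank 25 of 5,101 → 99.5.

## The synthetic tonsil

`TissueConfig` defaults describe the study conditions used throughout
the tests: a 2 × 2 mm field, 8 follicles (radius ≈ 140 ± 12 µm) with
40 µm mantles placed by rejection sampling, an 80 µm epithelial band,
and region-wise homogeneous Poisson cell placement (≈ 30k cells;
GC/mantle 0.013 µm⁻², T zone 0.0062 µm⁻², epithelium 0.009 µm⁻²).
Each follicle disk splits into LZ and DZ half-disks by a random chord.
Cell types are drawn from region-conditioned compositions (e.g. LZ:
52% LZ GC B, 17% Tfh, 12% FDC; T zone: 52% non-naive CD4, 10% Tfh).

Expression follows a negative binomial (mean/dispersion, dispersion 2.0)
with mean = baseline × fold(region, type) + ambient (0.02). The 200-gene
panel covers seven program classes — GC-Tfh-restricted (4 genes, the
planted analog of a GC-activation marker: expressed only by Tfh inside
GCs), pan-Tfh (16), GC-associated-unrestricted (16; 10-fold GC bias
among Tfh, the "classic GC marker" analog whose positive Tfh are
substantially extrafollicular), GC-B-restricted (20), FDC-restricted
(10), non-GC-Tfh (14), housekeeping (120, log-uniform baselines). The
panel is a fixed function of its own seed so genes are comparable across
tissue realizations.

Contamination is applied to clean counts in three channels:

- **Diffusion:** each transcript leaves its cell with probability
  λ = 0.1 and moves to a neighbor within r = 15 µm, chosen with
  truncated-Gaussian weights (scale r/2). Cells without neighbors retain
  their counts. Implemented as per-transcript multinomial reassignment,
  so per-gene totals are conserved exactly.
- **Segmentation swap:** 3% of cells exchange a Binomial(count, 0.3)
  share of each gene with their nearest neighbor (disjoint pairs);
  conservative by construction.
- **Vertical overlap:** 3% of cells additively receive a 50% thinned
  copy of a phantom cell drawn from the local region's composition and
  the same count model. This channel adds counts; the additions are
  logged per gene so conservation remains checkable.

λ and r are calibrated to the qualitative target that GC-B-restricted
genes acquire the spillover signature (GC-enriched in spatial Tfh,
Tfh-depleted in the reference) without displacing the GC-Tfh-restricted
program from the top PPV ranks.

The **dissociated reference** reuses the same programs without
contamination: lineage proportions typical of dissociated tonsil and a
latent per-cell region context (28% GC) standing in for the activation
states that survive dissociation. The **gene-activity matrix** is
log1p(planted mean) + Gaussian noise (sd 0.4), clipped at zero — a
deliberately simple monotone proxy for chromatin accessibility that
gives the meta-analysis a correlated second modality with known truth.

Ground truth recorded per run: each cell's pre-contamination region and
type; each gene's class and its planted in-GC positivity fraction among
Tfh (computed from the clean counts at threshold 1), which is the
reference value for PPV calibration at λ = 0.

### What the generator does not emulate

Transcript-level spot coordinates, optical noise, segmentation polygons,
cell-size variation, spatial gradients within regions, inter-sample
batch effects, and doublet-driven label errors. Passing tests show the
*statistical machinery* recovers planted structure under a plausible
contamination model — not that any particular real tissue satisfies that
model. Real analyses should treat the contamination defaults as
placeholders to be re-fit.

## Numerical and degenerate-input behavior

- All randomness flows from one seed through named substreams
  (geometry/types/counts/diffusion/swap/overlap), so stages re-run in
  isolation reproduce a full run; pipelines are byte-reproducible.
- Constant-valued genes get p = 1 (and log₂FC 0 for identical groups)
  instead of the 0/0 z-score.
- PPV ties rank by more positive Tfh first, then gene name; the ranking
  is invariant under monotone transforms of PPV.
- Samples without target cells get NaN distances with a warning; decay
  grid points with no cell within 3 bandwidths are reported missing.
- Masks: closing is padded so the image border is never eroded; the
  filled mask is a superset of the rasterized input and the operation is
  idempotent.
- Empty GC CN sets are an error; a GC annotation that matches no cells
  yields an all-false mask with a warning rather than an error.

## Problem sizes used in tests and the acceptance script

Ten seeds of the full default tissue (~30k cells, 200 genes) for ranking
and three-way recovery, twenty contamination-free seeds for PPV
calibration, 500 random instances against the exact rank-sum oracle, 100
random rasters against the flood-fill oracle, and 100 label-pair draws
for the AMI null. These sizes give stable pass/fail behavior at
desk-scale runtimes; the planted effects are strong enough that the
recovery rates are not near their thresholds.

## Known limitations

- CN annotation rules are tuned to the synthetic composition vocabulary;
  real datasets with different level-1 vocabularies need custom rules.
- The GC mask inherits the raster resolution: boundary cells within one
  bin of the true boundary can be misassigned (the dominant term in the
  ≈ 0.02 PPV calibration error).
- The exact rank-sum path is limited to group sizes ≤ 8 without ties;
  everything larger uses the asymptotic approximation, adequate at
  hundreds of cells but not for tiny pilot groups with heavy ties.
- Fisher's method assumes independent p-values across modalities; RNA
  and gene activity from the same cells violate this, so the meta p is
  an ordering device, not a calibrated error rate.
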