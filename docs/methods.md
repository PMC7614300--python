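# Methods

## The scientific setting

Sorted ATAC-seq of neural-tube progenitors yields a fragment-count
matrix over consensus peaks for samples indexed by cell type
(an NMP-like origin state plus the p0-1, p2, pMN and p3 progenitor
domains), differentiation day, agonist dose and replicate. The
pipeline asks which elements change accessibility between conditions,
groups the changing elements by their dynamics, infers which
transcription factors drive the changes from footprint/RNA coupling,
and classifies each cell type's regulatory strategy: *differential
binding* (shared open elements, distinct occupancy) versus
*differential accessibility* (private open elements). A separate
imaging arm quantifies lineage-traced p3/V3 cells in stained sections.

## Differential accessibility model

Counts are modeled as negative binomial with variance
`μ + αμ²` (α the dispersion). Per-sample depth is removed by
median-of-ratios size factors: the reference per element is its
geometric mean across samples, computed over elements with all counts
positive, and factor_j is the median ratio; factors are rescaled to
geometric mean 1. This estimator presumes a majority of non-changing
elements — on data where *every* element is differential it has no
anchor (the synthetic generator therefore plants a constitutive
background fraction, as real consensus peak sets have).

For a two-group comparison the test statistic is

```
log2FC = log2((mean_B + c) / (mean_A + c)),   c = 0.5
SE²    = Σ_g (q_g Σ_j 1/s_j + n_g α q_g²) / (n_g² q_g² ln²2)
p      = 2 Φ(−|log2FC / SE|)
```

on size-factor-normalized counts, with BH adjustment within each
comparison. The pseudocount c is half a fragment at reference depth;
it stabilizes fold changes of zero rows and is negligible at the
count levels the baseMean filter admits. (An earlier formulation of c
as `0.5/median(depth)` mixes a fragment-fraction scale into
normalized-count arithmetic; the package uses the normalized-count
scale throughout.)

**Dispersion.** `estimate_dispersion` gives the per-element
method-of-moments value `max(α_floor, (v − m)/m²)` (pooled
within-group variance v, grand mean m, floor 1e-8). At 3 replicates
per group this is far too noisy to plug into a Wald test (measured
type-I error ~0.12 at nominal 0.05). The default pipeline therefore
uses `pooled_dispersion`, a single value aggregated over elements:

```
α̂ = Σ_i (v_i − m_i) / Σ_i (m_i² − v_i / n)
```

The `v_i/n` term removes the `E[m²] = μ² + Var(m)` bias of the naive
denominator (without it α̂ is a few percent low). With this estimator
the measured type-I error at nominal 0.05 is 0.051–0.057 across
seeds — the small residual excess is the normal-tail approximation to
the ratio statistic at n = 3, not the dispersion estimate (plugging in
the true α gives 0.053–0.055). No fold-change shrinkage is applied;
the selection thresholds act on unshrunk estimates.

**Selection and counting.** Elements enter clustering when
`padj < 0.01` and `|log2FC| > 2` and `baseMean > 100`, all strict;
baseMean is the mean normalized count over the two compared groups
(not all samples — a flag could widen this, but the compared pair is
what the test sees). Summary counts of differential elements per
comparison use `|log2FC| > 1` (fold change > 2) by default, matching
the convention for bar-plot summaries; both thresholds are exposed.

## Clustering and regime classification

Selected elements are summarized as per-condition means of the
variance-stabilized matrix (`log2(count/factor + 1)` — a simple
monotone stand-in for a model-based VST, adequate because clustering
consumes z-scored profiles), then z-scored per element so clusters
capture the *shape* of dynamics, not amplitude (a flag disables the
scaling). Stage 1 is k-means with a deliberately large k₁ = 30
(k-means++ init, 10 restarts, fixed seed); stage 2 merges the 30
centroids by average-linkage hierarchical clustering under correlation
distance (1 − Pearson), cutting the tree to 9 clusters. Correlation
distance matches the "same dynamics" semantics; Euclidean/complete
variants are available. Clustering the centroids (not all elements)
keeps stage 2 deterministic and cheap; empty clusters cannot arise
because scikit-learn's k-means relocates them internally.

Cluster labels are rules on the z-scored centroids with
high ≥ +0.5 and low ≤ −0.5: high only in the origin state → `NMP`;
origin low and every later condition non-negative → `pan-neural`;
high confined to one progenitor with everything else low →
`<ct>-specific`, or merely moderate outside → `<ct>-enriched`;
otherwise `other`.

Regime classification: an element is *accessible in* a cell type if
its mean z-profile over that cell type's conditions exceeds +0.5; the
specificity fraction is the share of those elements lying in clusters
tagged specific/enriched for that cell type. Fractions above τ = 0.15
give `differential_accessibility`. τ is a package default calibrated
on the simulator, not a measured biological constant, and is exposed
prominently; on planted data the fraction is near 1 for the unique
cell type and near 0 for shared ones, so calls are insensitive to τ
over a wide range.

PCA ranks elements by variance across samples (default top 30,000),
centers per element and decomposes by SVD; coordinates are `UΣ` over
samples.

## Footprints and driver ranking

The footprint score of an insertion profile is
`log2((flank + 1)/(center + 1))` over a center window with adjacent
flanks — positive means protection. Imported footprint score tables
(e.g. from bias-corrected footprinting tools) feed the same downstream
operations; the transposase sequence-bias correction itself is out of
scope. Differential footprints are robust z-scores of per-motif score
differences against the all-motif background
(median / 1.4826·MAD, two-sided normal tail); score "fold change" is
interpreted as a difference since the scores are already log-scaled.
Variable motifs are the union, over comparisons, of the top 5% by
|Δ| and the 5% smallest p (ceiling counts, name-tie-broken); the
union reading of "or" is used.

Motifs are grouped into archetypes by PWM similarity — the maximum
over ungapped offsets and reverse complement of the mean column-wise
Pearson correlation (≥ 4 aligned columns) — clustered by average
linkage and cut at similarity 0.8. A published motif→archetype mapping
file, when supplied, always wins over de-novo clustering. Archetype
scores are the mean over member motifs (mean chosen over max: every
member is evidence for the shared specificity; a flag selects the
aggregation). Candidate drivers are ranked per archetype by Pearson
correlation between the archetype score and each member TF's RNA
across shared conditions (≥ 3 required); zero-variance genes rank last
and are flagged rather than silently scored 0.

## Imaging quantification

Nuclei are segmented on DAPI: Gaussian smooth (σ = 1), global Otsu
threshold (256-bin), 8-connected components, area filter. Channel
means per nucleus are thresholded by Otsu on the *per-nucleus* values
(not raw pixels; a quantile mode exists for skewed data); the full
pipeline pools nuclei across sections before thresholding so a section
containing only positives cannot split its own unimodal distribution.
Classification: SOX2+/NKX2.2+ → p3; NKX2.2-only → V3; everything else
`other`; tdTomato positivity by its own threshold. Positional QC
formalizes the qualitative rule that NKX2.2 signal far from the p3
domain is antibody background: NKX2.2+ cells farther than a configured
distance from the domain center are excluded. The center defaults to
the coordinate-wise **median** of NKX2.2+ cell positions — an
intensity-weighted centroid is dragged toward exactly the far
background cells the rule should remove, so a robust location is used;
an explicit center can be passed. No watershed splitting by default
(the generator guarantees separation); real clumped data would need
the optional distance-transform variant.

## The synthetic generator

Defaults model the study design: NMP at days 3–4 (so its program is
reachable by the within-timepoint/within-cell-type comparison plan)
and four progenitors at days 4–6 at their characteristic agonist
doses, 3 replicates, 14 conditions. 30% of elements are constitutive
background; the rest carry one of nine planted programs (origin,
pan-neural, p3-specific, shared-progenitor, late, transient and
single-day waves), chosen pairwise-dissimilar (binary-profile
correlation ≲ 0.6) because collinear programs are not recoverable by
any clustering of dynamics. Counts are NB with baseline 50, open
elements 2³-fold higher (effect_log2fc = 3), dispersion 0.2, and
per-sample library factors log-uniform in [0.5, 2]. Footprint tables
couple archetype 1 to the unique cell type (the planted pioneer);
every archetype has one driver gene at expected correlation 0.9 and
independent decoys; RNA is on an affine log-expression scale so
planted correlations survive. Section images are flat-background disks
with class-specific channel means (on 180 / off 20, separation 160),
nuclei placed by rejection sampling at minimum center distance
2·radius + 3 px (touching disks at exactly 2·radius would merge under
8-connectivity after smoothing). The two-group generator for
power/calibration studies uses baseline 400 so that 8-fold-*down*
elements remain above the baseMean > 100 floor and power measurements
reflect the test, not the coverage filter.

What the generator does **not** emulate: read-level data, transposase
sequence bias, GC/mappability structure, overlapping or irregular peak
geometry, dispersion–mean trends, doublets or staining gradients in
images. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to every artifact of
real data.

## Validation studies and problem sizes

All studies live in `regland.benchmarks`, are driven by a single seed,
and complete in ~15 s total on one CPU:

| study | size |
|---|---|
| Wald null calibration | 20 × 1000 elements, 3 vs 3, α = 0.2 |
| DA recovery | 3 × 2000 elements, 10% planted at log2FC = 3 |
| clustering recovery/stability | 1800 elements, 9 programs, 5 seeds |
| regime classification | 20 end-to-end simulations |
| driver ranking | 200 simulations, 8 archetypes, 5 decoys, 12 conditions |
| overlap oracle | 1000 vs 1000 random intervals (exact) |
| hypergeometric oracle | all N = 10 subset enumerations (≤ 1e-12) |
| imaging | 6 noise-free + 50 noisy sections |
| numerics | PCA 50×6 vs eigh (1e-8); size factors vs planted (10%); BH vs step-up |

## Known limitations

* The Wald test is slightly anticonservative (~0.055 at nominal 0.05)
  at 3 replicates; this is the normal-tail approximation and is
  documented rather than patched with an ad-hoc df correction.
* Median-of-ratios normalization degrades when the differential
  fraction is large; the paired condition-specific bias then leaks
  into fold changes.
* A handful of false-positive selections with flat profiles can
  capture k-means centroids after z-scoring (their profile is pure
  amplified noise) and occupy merged clusters at the fixed 9-cluster
  cut; recovery of the planted partition is exact when profiles are
  built from truly dynamic elements.
* Cluster labels are rule-based on centroids; programs spanning
  several cell types (late waves, shared-progenitor blocks) land in
  `other` by design.
* Hypergeometric cluster enrichment is a statistical companion to
  coverage heatmaps, reported as a package addition, not a quantity
  the original analysis computed.
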