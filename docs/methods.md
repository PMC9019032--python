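# Methods

This note documents the models, defaults and numerical choices behind
`isletid`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic data model

Counts are negative binomial, `y ~ NB(mean = μ, var = μ + φμ²)` with a
single dispersion `φ` (default 0.4, a typical droplet-data value). For gene
*g* in cell *c* of dataset *d*:

```
μ_gcd = base_g · effect_gd(type(c)) · depth_d · s_c
```

* `base_g` — lognormal per-gene base means, drawn once from the master
  seed: background genes lognormal(log 0.5, 0.5); markers
  lognormal(log 1.0, 0.3). Markers sit on a higher, tighter base because
  identity genes are well-expressed in real tissue; a marker whose base
  mean is far below one count per cell could never be called reproducibly
  at realistic depths.
* `effect_gd` — a marker of type *t* multiplies its mean by
  `exp(logFC)` (default logFC = 1.0, natural log) in type-*t* cells, but
  only in datasets where its independent Bernoulli(*r*) activity draw
  succeeded. The default tier structure per type is 30 markers at r = 1.0,
  30 at 0.6 and 20 at 0.3, emulating markers of high, medium and poor
  cross-dataset reproducibility. The activity matrix is fixed by the master
  seed and exported as truth.
* Hormone genes (one per type) are two-component lognormal: per-cell mean
  `exp(N(log 40, 0.35))` in the own type, `exp(N(log 0.25, 0.35))`
  elsewhere — high enough to dominate a cell's hormone readout and to make
  the log-normalized distribution robustly bimodal, low enough that
  off-type leakage stays below any sensible threshold.
* Mitochondrial genes (10) carry a fixed 5% of each cell's expected
  library; per-cell size factors are lognormal(0, 0.3).
* Depth regimes: the default seven datasets comprise two "umi" datasets at
  depth ×1 and five "fulllength" datasets at depth ×6, mirroring a typical
  mix of shallow UMI and deep full-length chemistries. The pipeline treats
  the regimes identically after normalization except for the DE test
  choice (NB on counts for UMI, hurdle otherwise).
* Doublets: `round(rate · n)` column sums of two distinct random cells
  (default rate 0.05). Bihormonal hybrids: 2% of the donor type
  additionally *gain* the acceptor hormone (own-type distribution) and the
  first ten acceptor markers (the marginal effect mass), by adding freshly
  drawn counts — expected counts never decrease, so hybrids are strict
  supersets of their mono-hormonal parents.

Seeds: one master seed; children derived as
`SeedSequence((seed, stage, index))` with fixed stage codes, so every
dataset, doublet draw and evaluation replicate is independently
reproducible.

What the generator does **not** emulate: transcriptome-wide co-expression
structure, ambient RNA, batch effects beyond a depth multiplier, gene
length bias in full-length data, or empty/low-quality cells. Passing tests
therefore certify the *pipeline logic and statistics* against planted
truth, not robustness to every artifact of real data.

## Cell typing

QC keeps cells with total counts ≥ `min_counts`, detected genes ≥
`min_genes` and mitochondrial fraction strictly below `max_mito_fraction`.
The synthetic default (100 / 50 / 0.5) is scaled to the simulated library
sizes (~600–5000 counts); for real data the classic 2000 / 1000 / 0.15
setting applies and is what the unit tests exercise at the boundary.

Normalization is `log(1 + 10⁴ · count / total)` in natural log; all logFC
values in the package are natural-log units.

Doublet scoring spikes synthetic doublets (sums of two random cells) to
25% of the augmented pool, embeds everything by PCA (20 components) of the
log-normalized matrix, and scores each cell by its fraction of synthetic
neighbours among k nearest, converted to a calibrated probability via the
pool odds (a neighbourhood matching the pool composition scores 0.5). Two
parameterizations (k = 10 and k = 30) stand in for the two published
detectors; each flags its top 5% (the expected rate) and the union is
removed. Homotypic doublets are partially detectable because averaging two
cells shrinks within-cluster noise, concentrating both real and synthetic
doublets near cluster centres in the higher PCA dimensions.

Hormone thresholds: Gaussian KDE with Silverman bandwidth on a 512-point
grid over the data range; modes are `find_peaks` maxima with prominence ≥
5% of the density maximum (the grid is padded so boundary modes count);
the threshold is the density minimum strictly between the two highest
modes. With fewer than two modes the method falls back to an Otsu-style
between-class-variance split and records the `otsu_fallback` tag.
Classification is inclusive: expression equal to the threshold counts as
expressing. Constant input is an error — no threshold is definable.

Allocation: k-means (k = number of hormone genes) on 20 PCs produces
clusters; each cluster is called to the majority type of its mono-hormonal
cells ("other" when fewer than 20% of its cells are mono-hormonal). The
final label is the cluster call, overridden by a single mismatching
hormone; two or more hormones over threshold ⇒ *bihormonal*; no hormone in
an "other" cluster ⇒ *other*. Clustering is deliberately pluggable —
externally supplied labels can replace it everywhere.

## Differential expression

Both tests share the design `[1, group, log(total), n_detected]`
(standardized nuisance covariates; donor added when more than one donor is
present and requested) and are solved by IRLS batched across genes: the
per-gene normal equations are stacked and solved in one call, which is
exact IRLS, not an approximation.

* **NB LRT**: per-gene dispersion by method of moments from a Poisson fit
  (`φ = Σ((y−μ̂)² − μ̂) / Σ μ̂²`, clipped to [1e−8, 10]), then NB fits of
  the full and null models at fixed dispersion; LRT ~ χ²₁.
* **Hurdle LRT**: logistic IRLS on detection plus 0/1-weighted least
  squares on positive values; the two LRTs add into a χ²₂ statistic.
  Perfectly separated genes are handled by clipping the logistic linear
  predictor at ±12, which leaves the LRT large but finite.

Only genes expressed in ≥10% of either group are tested, and the
multiple-testing correction (Bonferroni by default; BH available) runs
over tested genes — the correction universe is a declared choice.

LogFC is computed uniformly as
`log((mean_norm_A + 1) / (mean_norm_B + 1))` on library-size-normalized
(×10⁴) group means, so the same effect scale applies across tests.
Derivation filter: positive genes with logFC ≥ 0.5 and padj ≤ 0.05.
Evaluation-rank filter: both directions at |logFC| ≥ 0.1. Reporting order:
padj asc, |logFC| desc, gene id asc.

Known caveat: under library-size normalization, cells that gain a
high-mass gene (e.g. a second hormone) show a mild apparent *down*-shift
of everything else (~−0.1 to −0.25 logFC for well-expressed genes). This
compositional dilution sits below the derivation filter but can reach
significance at the loose 0.1 threshold; the hybrid-cell "gains only"
property is therefore stated (and tested) at the derivation filter.

## Integration, genesets, GSEA, optimization

Integration aggregates only contributing analyses (missing ≠ zero):
`avgPadj = 10^(−mean(−log10 p))` (the geometric mean; p floored at 1e−300
first), `rank score = −log10(avgPadj) · avgLFC`, ordering by `n_analyses`
desc, rank score desc, gene id asc (the lexicographic tiebreak makes the
order total and permutation-invariant).

Geneset level *k* = genes with `n_analyses ≥ k`, k = 1..D·(T−1); sizes
outside [40, 500] are ineligible (bounds inclusive). The overlap partition
records full membership signatures; "pairwise shared" counts are genes in
*exactly* two sets, which is the arithmetic that makes exclusive +
pairwise counts sum to each geneset's size. Ortholog mapping is
table-driven: one-to-many expands, unmapped genes drop, output is
de-duplicated and sorted.

The GSEA engine is self-contained pre-ranked GSEA: scores are
`−log10(padj)` floored at 1e−300 and **signed by fold-change direction**
(unsigned ranks would score depleted genesets as enriched; depletion must
come out negative). Weight p = 1. ES is the signed maximum deviation of
the running sum (hits weighted by |score|, misses by 1/(N−m)); an exact
|max| = |min| tie prefers the positive peak, and ties in scores keep input
order under a stable sort. The null is gene-label permutation at equal
geneset size (vectorized; n_perm default 1000, seed mandatory);
NES = ES / mean(same-sign null ES); nominal p uses the (1+count)/(1+n)
convention. FDR q across genesets uses the standard pooled-null NES
normalization. A geneset retrieving <15 or >500 genes of the ranked list
is not scored and carries an explicit failure status; the gene retrieval
rate (GRR) is reported regardless.

Evaluation grid: 3 held-out datasets × (T−1) opponents per target type (9
evaluations in the 4-type design), generated from the same truth with a
disjoint seed path and processed by the *pipeline's own* cell typing.
EM = mean NES × mean GRR over successful evaluations, zeroed outright when
any evaluation fails — the strict reading of the failure rule; the
per-evaluation breakdown is still reported. Selection is argmax EM with
ties resolved toward the higher (more specific) level. Benchmarking runs
paired two-sided Wilcoxon signed-rank tests (exact 2ⁿ enumeration for
n ≤ 12 with average ranks; normal approximation with tie and continuity
correction above), dropping pairs with a failed member rather than
imputing zeros.

## Problem sizes

The default study design is 7 datasets × 4 types × 100 cells/type
(~1134 genes) plus 3 evaluation datasets; the full chain runs in ~20 s on
one CPU. The replicate-stability analysis uses the same design with 50
cells/type, 400 background genes and 150 permutations per GSEA so that ten
independent replicates stay cheap; geneset sizes are kept at study scale
there so the 15-gene matching gate is never the binding constraint. The
scaled-down examples in `examples/` shrink the marker block too and scale
the eligibility bounds accordingly (`min_geneset_size=15`), since 40-gene
bounds are meaningless when whole genesets hold ~40 genes.

## Limitations

* The hurdle model is a generic two-part LRT, not a re-implementation of
  any specific published hurdle model's shrinkage or model matrix.
* Dispersion estimation by moments is slightly anti-conservative for genes
  that are a large fraction of the library (the library-size covariate
  partially explains the gene's own noise); hormone-scale genes are the
  only such genes here and are never borderline calls.
* K-means with a known cluster count replaces graph-based community
  detection and cluster-tree merging; for real data, externally supplied
  cluster labels are the intended entry point.
* The FDR q of the GSEA engine follows the pooled-null recipe; desktop
  implementations differ in detail and q-values are not compared anywhere
  in the selection logic (selection uses EM only).
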