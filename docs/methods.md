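# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Genotype–environment association

**RDA.** Genotypes are encoded as minor-allele counts (0/1/2), centered but
not scaled — unscaled loadings keep loci of similar frequency comparable
and avoid amplifying noise at rare alleles; scaling is available as an
option. The fitted matrix is the orthogonal projection of the centered
genotype matrix onto the column space of the centered predictors, computed
by least squares (no explicit normal-equations inverse). SNP loadings are
right singular vectors scaled by singular values over √(n−1); biplot
scores are correlations between predictors and fitted site scores.
Predictor collinearity is detected via matrix rank and reported with the
offending pair. The outlier rule flags loci more than `sd_threshold`
(default 3) standard deviations from the mean loading on any retained
constrained axis; under a standard normal loading null this flags ≈ 2Φ(−3)
≈ 0.27% of loci per axis, which the tests verify against a binomial
interval.

**Latent-factor association.** A transparent stand-in for latent-factor
mixed models: factors are the first K principal components of the genotype
matrix after regressing out climate, then each locus is fit by OLS on
[intercept, climate, factors]. Test statistics are calibrated by genomic
control, λ = median(z²)/0.4549, with calibrated p-values from χ²₁ and BH
q-values **per climate variable** (union over variables afterwards; the
alternative — pooling variables before FDR — is a defensible variant, but
per-variable control matches how the two climate axes are interpreted
separately downstream). Two calibration regimes matter:

- *Unconfounded climate* (climate independent of population structure):
  λ stays near 1 (observed ≈ 1.05–1.25 at 10 populations, n = 300) and the
  false-positive rate is far below the nominal FDR.
- *Confounded climate* (climate varies mostly among populations, as with
  clustered roost sampling): λ is large (the climate-aligned structure
  cannot be separated from climate), and genomic control absorbs the
  inflation. FDR control holds in both regimes; power is lower in the
  confounded one. This mirrors the behavior of the methods it stands in
  for.

**K selection** uses the eigenvalue scree: K is placed at the largest
consecutive eigenvalue drop, provided that drop ratio exceeds 2 (below
that, the scree is treated as structureless and K = 0). The threshold of 2
cleanly separates Balding–Nichols structure eigenvalues from the
Marchenko–Pastur bulk at the sample sizes used here.

**Intersection.** Within each method, candidates are unioned over the two
climate variables first, then intersected across methods on locus ids.
Each candidate is assigned to the climate variable with the largest
absolute genotype correlation; direction is that correlation's sign.

## Adaptive classification

Scoring refits the RDA on candidate loci only and takes site scores on the
constrained axis with the largest absolute temperature biplot score,
sign-fixed so the temperature vector points positive (hot–dry). The
individual threshold t = 0.25 SD (default) creates an intermediate band;
t = 0 degenerates to a sign split. Population labels use only
non-intermediate members with a 0.6 majority rule; populations under 3
individuals are flagged low-confidence. Reversing the axis convention
swaps hot/cold labels exactly, and monomorphic loci cannot move scores
(both are tested).

## Ensemble niche models

Three in-house algorithms replace the large committee of a conventional
ensemble platform, so every member is fully specified:

- **Envelope**: fraction of variables inside the presence
  [5th, 95th]-percentile range — bounded, coarse, often below the ensemble
  cutoff (which is fine; it then simply drops out).
- **Quadratic logistic**: ML logistic regression of presence (1) vs
  background (0) on linear + squared features.
- **Maxent-like**: L1-penalized logistic on linear + squared + pairwise
  product features; the suitability score is exp(η) rescaled by its
  maximum over the cells being predicted (raw normalization, no cumulative
  transform). At zero penalty it coincides with the logistic fit on the
  same features (tested to 1e−4 on coefficients).

Both regression members **clamp** predictors to their training range at
prediction time — the standard guard against polynomial extrapolation into
novel (future) climates; without it, convex fitted surfaces can explode in
warmed cells.

Evaluation uses random 70/30 presence (and background) splits — 10
replicates, 5 when presences < 50 — rank-based AUC, and TSS maximized over
101 evenly spaced thresholds (ties → lowest threshold). Members with mean
TSS ≥ 0.4 enter the ensemble with TSS-proportional weights; the weighted
mean of member outputs already lies in [0, 1], so no further rescaling is
applied (a post-hoc rescale would decouple the stored binarization
threshold from future projections). The binarization threshold is the
TSS-optimal threshold of the ensemble's scores on the pooled
presence/background data; it is reused unchanged for future projections so
range change is measured against one consistent rule. Future projection
predicts on each pseudo-GCM stack, averages per cell (unweighted — the
merge operator is a free choice), then binarizes. Null models refit the
same pipeline on random presence draws of the observed size; a model beats
random when its AUC exceeds the null maximum (p = 1/(n_null+1)).

Niche overlap (Schoener's D) is computed on suitability surfaces
normalized over the shared geographic support; an ecospat-style
occurrence-density variant in environment space is deliberately out of
scope. The similarity test pools the two occurrence sets, permutes labels
preserving sizes, refits both models against one shared background, and
reports p(lower) = (1 + #{D_null ≤ D_obs})/(n_perm + 1).

## Connectivity and rescue

Reclassification tables map landscape layers to costs in [1, 100]
(piecewise-constant or linearly interpolated); combination is cellwise
mean by default (sum/product variants rescale affinely into [1, 100]).
The raster graph uses 8-neighborhood by default, edge conductance = mean
of the two cells' conductances, diagonal conductances divided by √2.
Effective resistances are computed by grounding one node per connected
component, LU-factorizing the reduced Laplacian once, and solving per
focal pair; disconnected pairs are recorded as infinite with a warning.
Current density is the Circuitscape-style per-cell ½ Σ|incident branch
currents|, accumulated with equal weight over all source–target pairs
(self-pairs skipped). The implementation is verified against a dense
Moore–Penrose pseudoinverse oracle (hermitian mode — the generic SVD path
of `numpy.linalg.pinv` is measurably inaccurate on ill-conditioned
Laplacians), series/parallel closed forms, Kirchhoff splits, conservation,
the metric property, and Rayleigh monotonicity.

IBR regression reports Mantel r (Pearson over the off-diagonal upper
triangle; one-sided p by simultaneous row/column permutation) plus OLS
R²; candidate surfaces are ranked by R². Mixed-model alternatives (MLPE)
are a noted extension, not implemented. Rescue potential = current density
with hot-dry locations as sources and cold-wet as targets, summarized per
target by mean effective resistance from all sources.

## F-statistics

Weir & Cockerham (1984) variance components (a, b, c), vectorized over
loci; multilocus θ is the ratio of summed components (ratio-of-averages),
which is the stable choice for sparse RAD data. Negative per-locus
components are retained; the multilocus estimate is reported as computed.
Linearization θ/(1−θ) clamps the denominator at 1e−6. Loci that are
monomorphic for a pair, or where a population has fewer than two genotyped
individuals, are excluded from that pair's sums.

## Synthetic data: what it emulates, and what it does not

Climate layers are a directional linear gradient plus Gaussian-smoothed
white noise (kernel SD = autocorrelation range), standardized per layer —
enough spatial structure for Moran's-I and niche-model tests, not a
geostatistical simulator. Futures are deterministic mean shifts (the
spatially varying anomaly is demeaned so the realized shift is exact);
distinct shift sets stand in for distinct GCMs. Neutral genotypes follow
the Balding–Nichols island model (ancestral p ~ U(0.05, 0.95); population
frequency ~ Beta with mean p, variance p(1−p)·F_ST), which makes the
realized multilocus θ analytically checkable (±0.05 of target at ≥1000
loci). Adaptive loci act marginally and independently — individual-level
allele frequency = logistic(logit(p) + slope·climate) — with no linkage,
no selection dynamics, and no coalescent history. Occurrences are drawn
with probability proportional to a logistic suitability surface (optional
quadratic terms give unimodal niches). Consequently, passing tests show
the estimators recover *this* generative structure; they do not speak to
linkage disequilibrium, allele surfing, historical range dynamics, or
sampling biases of real occurrence data.

### Default study conditions

GEA/classification recovery: 64×64 landscape, two opposing climate
gradients, 10 populations × 30 individuals (roosts at random cells,
individuals jittered ±3 cells), 2000 neutral + 20 adaptive loci,
F_ST = 0.1, cline slope 2 log-odds per climate SD, 20 fixed replicate
seeds. The range-loss comparison uses a 40×40 landscape with orthogonal
gradients: the hot-dry niche is warm-open (monotone heat tolerance — the
group already occupies the warmest cells, so no upper limit is observable),
the cold-wet niche is unimodal at −0.7 SD, both share a narrow
precipitation band; the full-species record set (n = 120) is dominated by
core-climate occurrences with the adapted margins as minorities (as in
real datasets, where only a fraction of individuals carry extreme adaptive
genotypes), group sets are n = 40 each; warming shifts the temperature
layer by +1.0/+1.5/+2.0 SD (three pseudo-GCMs) with mild drying (−δ/4).
These grid and sample sizes were chosen so a full 20-replicate experiment
suite runs in well under a minute on a single CPU while preserving the
qualitative regime of interest. IBR experiments use a 30×30 landscape,
three candidate surfaces (two layers and their mean, costs interpolated
between breakpoints), 12 focal sites, and noise at 25% of the
resistance-distance spread.

## Degenerate inputs and tie rules

Missing genotypes impute to the per-locus modal genotype, ties toward the
lower count. Genepop minor-allele ties break toward the larger allele
code. Zero-variance loci get p = 1 with a flag. TSS threshold ties take
the lowest threshold. The correlation-screening step drops, from the worst
pair, the layer with the larger mean absolute correlation to all others
(ties by layer order). All generators and analyses are bit-reproducible
given a seed; the pipeline derives every stage seed from one top-level
seed and reruns are byte-identical (tested).

## Known limitations

- The latent-factor method is a PCA-plus-genomic-control approximation,
  not the exact estimator of any published package.
- The ensemble has three members; AUC/TSS values are not comparable to
  ten-algorithm platform ensembles on real data.
- Niche overlap is geographic-support based; environment-space density
  overlap is not implemented.
- Resistance surfaces in the pipeline demo are derived from synthetic
  layers; no real land-cover semantics attach to them.
- With very diffuse niches (suitable area ≳ half the study region), no
  ensemble member may clear the TSS cutoff; the error reports the best
  member TSS, and the cutoff is configurable.
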