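# Methods

`covariome` implements a proteogenomic co-variation analysis for cancer
cell-line panels: starting from feature × sample abundance matrices
(proteins, phosphopeptides, mRNA), it builds protein co-variation networks,
evaluates them against annotated complexes and interactions, detects
weighted-network modules, estimates net phosphorylation, quantifies the
impact of somatic mutations and copy-number alterations, maps QTL across
molecular layers, derives proteomic subtypes and fits multi-omic
drug-response models. This note documents the models, the numerical
choices, and what the synthetic cohort used for testing does and does not
emulate.

## Abundance scaling

Isobaric-labelling intensities are comparable only after two
normalizations: every sample (column) is scaled to carry the same total
signal, and every feature (row) is scaled so its mean over non-missing
entries is 100, which places a 10-sample profile on the 0–1000 scale used
throughout. A single column-then-row pass leaves the column totals slightly
unequal again (row scaling perturbs them by ~n^(-1/2)), so
`scale_intensities` alternates the two steps to their joint fixed point
(tolerance 1e-10, ending on a row step). At the fixed point both
postconditions hold simultaneously and the operation is idempotent; the
first iterate is exactly the classic single pass, and the fixed point
differs from it only at the percent level. All-zero or all-missing rows
cannot be row-scaled and are dropped with a log entry.

Coefficients of variation (CV = SD/mean, percent, sample SD with n−1) are
computed on the linear scaled intensities — CV is scale-dependent and a log
transform would distort it — while every correlation downstream uses
log2(scaled + 1). The smallest reliably detectable fold change is taken as
1 + 2·CV/100 (two baseline SDs), e.g. 1.5-fold at CV = 25%.

## Co-variation networks and modules

Pairwise Pearson correlations are computed on log2 intensities with
pairwise-complete observations (default floor: 10 shared samples), over
features quantified in ≥ 80% of samples. The implementation uses masked
matrix products, so a 2000-feature panel costs a handful of p × p matmuls.

The weighted network follows the WGCNA recipe with deliberate
simplifications:

* **Adjacency** is unsigned, `|r|**power`. A signed option exists, but in
  co-variation networks of this kind the vast majority of retained edges
  are positive and the unsigned form is the method's default.
* **Soft power** is the smallest power whose connectivity distribution has
  a scale-free fit R² ≥ 0.8 (10-bin log–log regression, sign-flipped for
  increasing fits), falling back to 6 when no power qualifies.
* **Topological overlap**: TOM_ij = (Σ_u a_iu·a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij), symmetric, clipped to [0, 1], unit diagonal.
* **Modules** come from average-linkage clustering of 1 − TOM with a
  *static* cut at 0.995 × the highest merge height, followed by a minimum
  module size of 3; smaller clusters are labelled 0 (unassigned). The
  static cut replaces dynamic tree cutting: it is simpler, deterministic
  (ties broken by feature order through the linkage), and behaves correctly
  in both regimes that matter — planted blocks merge far below the cut and
  survive, while pure-noise features only merge near the root and stay
  unassigned. The cut height is configurable.
* **Eigengenes** are the first principal component of the z-scored member
  profiles (missing entries imputed at the feature mean), sign-anchored so
  the mean correlation with members is positive, and scaled to unit sample
  variance. Variance explained is the top squared-singular-value share.
* **Enrichment** is a one-sided hypergeometric test of each gene set in
  each module against the analyzed universe, Benjamini–Hochberg corrected
  across all (module, set) tests.

Network evaluation uses the correlation as a classifier score for known
interaction pairs. The AUC is computed by the Mann–Whitney rank identity
with tie-averaging, which equals an exhaustive concordant-pair count with
tie-halving (asserted against that oracle in the tests); the TPR/FPR sweep
comes from the standard threshold sweep. Negatives default to all
non-annotated pairs among the annotated features.

## Net phosphorylation

Phosphopeptide profiles ride on their parent protein's abundance. Each
peptide's log2 profile is regressed (OLS) on the parent's log2 profile over
their shared samples and replaced by the residuals, which are exactly
orthogonal to the parent profile and mean zero. Peptides without a usable
parent (unmapped, too few shared samples, zero-variance parent) are passed
through mean-centered and flagged rather than dropped. Co-phosphorylation
networks are pairwise correlations of the residual profiles restricted to a
supplied kinase/phosphatase peptide list, with two-sided correlation-test
p-values (t transform, n−2 df) and BH correction over the full pair list;
the regression is per-peptide, matching the one-profile-at-a-time reading
of the procedure.

## Mutation and CNA impact

The scan statistic is the two-group one-way ANOVA of mutated vs wild-type
samples, computed as the pooled-variance t (F = t²); effects are
differences of log2 group means, so planted and reported effects share a
scale. Multiplicity is controlled by a **pooled-permutation plug-in FDR**:
labels are permuted within each feature's own test (preserving its group
sizes and missingness), permuted |t| values are pooled across features, and
q(t) = (expected null count ≥ t) / (observed count ≥ t), monotonized to be
non-increasing in t and capped at 1. Pooling was chosen over per-feature
nulls because the per-feature permutation distribution at 50 samples is too
coarse for q < 0.1 decisions; with ~10³ features and 500 permutations the
pooled null has ~5·10⁵ draws. Genes mutated in all or none of the samples
with data are untestable and logged, not errors. Calibration is verified on
global-null scans (≤ 1% of features called at q < 0.1 across 20 cohorts).

LoF scans use the loss-of-function classes (frameshift, nonsense, in-frame,
splice site, start/stop-codon loss); driver scans require ≥ 5 mutated
lines. Zygosity effects are per-(gene, sample) deviations from the
wild-type mean, stratified het/hom; the C-terminus position trend is a
Spearman correlation of relative position vs effect. `regress_out` computes
per-gene OLS residuals of one layer on another (protein on mRNA, mRNA on
protein, or log-IC50 on the efflux covariate) and is exact: residuals are
orthogonal to the covariate to floating-point precision.

Propagation subnetworks connect LoF-downregulated proteins (p < 0.05,
negative effect — the hit threshold is deliberately looser than the scan
FDR, and both are exposed) to partners that are both annotated interactors
and strongly co-varying (TOM weight ≥ the export threshold, default 0.02).

QTL mapping regresses abundance on a binary variant indicator per
(variant, gene) pair; with a binary regressor this is identical to the
two-group ANOVA (asserted to 1e-9 in the tests). BH q-values are computed
within each layer, and replication between layers restricts both scans to
the common (variant, gene) universe, recomputes q inside it, and reports
the fraction of layer-A discoveries (q < 0.1, and at the relaxed 0.3
cutoff) reaching q < 0.3 in layer B, in both directions. No covariates are
included: population-structure correction is not meaningful for a
50-cell-line panel.

## Subtypes and drug response

Subtyping uses the top 30% most variable proteins without missing values
(SD of the log2 profile), then consensus k-means: 250 (default) k-means
runs per k on a random 80% sample subset of the row-standardized data,
consensus_ij = co-clustered / co-sampled. For the number of classes the
consensus-CDF-area curve and its relative gains are computed and reported,
but k itself is chosen by the elbow of the **PAC** curve (proportion of
ambiguous clustering, consensus entries in (0.1, 0.9)): the k with the
largest relative PAC drop from k−1, with a fallback to the smallest k when
no drop reaches 1.5× (no stable multi-class structure). The delta-area
elbow was tried first and rejected: on simulated data its curve for a
planted five-class cohort and for a homogeneous cloud are nearly
indistinguishable, a documented weakness of that rule, whereas the PAC drop
separates the two regimes cleanly. Final labels come from average-linkage
clustering of 1 − consensus at the chosen k. The MSI differential test is
Welch's t per feature with the same pooled-permutation FDR.

Drug models are elastic nets per (drug, layer) under nested
cross-validation: the outer 10-fold loop yields out-of-fold predictions;
the inner 5-fold `ElasticNetCV` picks the penalty (20-point alpha path,
l1_ratio 0.5 by default); features are standardized inside each training
fold only. A model is *predictive* when the Pearson correlation between
out-of-fold predictions and observed log2 IC50 exceeds 0.4 — out-of-fold
scoring keeps that filter from rewarding overfit models, which matters at
n = 50. Constant responses or constant predictions give r = NaN and a
non-predictive flag. Permuted-response controls run at ≤ 5% false flags.

Efflux correction regresses each drug's log2 IC50 on the mean of the
z-scored log2 profiles of the two efflux transporter genes (ABCB1/ABCB11
analogues) and refits the models on the residuals. The census of predictive
models is kept at the (drug, layer) level; after correction the *cumulative*
set of ever-predictive models grows when response determinants were masked
by efflux — note that for any single model the achievable correlation can
only decrease when predictable variance is removed, so the correction's
value is in the newly revealed models, not in raising per-model r. The
low/high efflux grouping for the per-drug association test is a median
split of the covariate.

## The synthetic cohort

`synthetic.generate_cohort` emits a 50-sample, 2000-protein panel (plus
mRNA, 400 phosphopeptides, mutations, binary CNAs, IC50s, annotation sets
and replicate measurements) with a `GroundTruth` ledger. Its defaults are
the study conditions for the test suite:

* **Complexes**: 40 latent factors with gene loadings √0.6 (± 5% jitter),
  giving within-complex pairwise r ≈ 0.6; every fifth complex carries one
  outlier subunit with halved loading. Complex membership is emitted as GMT
  sets and as a known-interaction pair list.
* **mRNA coupling**: per-gene target correlation ~ N(0.5, 0.15²) clipped to
  (−0.95, 0.95), realized by mixing the protein's latent core with
  independent noise; realized correlations regress on targets with slope
  1 ± 0.1. Per-gene mRNA dispersion is coupled to protein dispersion so
  variable mRNAs correspond to variable proteins.
* **Mutations**: 20 LoF genes (complex hubs; 8–16 mutated lines each,
  random het/hom) with multiplicative effects on intensity — additive on
  log2, −1 SD (het) or −2 SD (hom) in units of the feature's own noise SD;
  the same shift hits the gene's mRNA (direct effects are transcriptional
  and post-transcriptional), and a fraction (default 0.5) propagates to
  complex partners at the protein level *only*, emulating
  transcript-independent propagation through complexes. Mutated positions
  are uniform on [0, 1] with an optional linear C-terminal attenuation
  (default off). Missense genes carry zero effect except two "stabilizing"
  genes with a +1.5 SD protein-only effect (TP53-like).
* **CNAs**: 10 regions × 4 genes, alternating amplification/loss, ±0.5
  log2 dosage on both layers in 5–12 altered lines.
* **Subtypes**: 5 balanced classes shifting disjoint 50-protein blocks by
  +2 SD; signature proteins are drawn from the upper half of the
  feature-SD range — subtype markers are highly variable by construction,
  which is precisely why top-variance feature selection retrieves them.
  Subtype 1 doubles as the MSI-high group.
* **Phosphopeptides**: log2 peptide = parent protein log2 + residual;
  8 kinase groups of 5 peptides share latent residual factors (loading
  0.85), one peptide anti-regulated; remaining peptides are noise on their
  parent.
* **Drugs**: an efflux-transporter pair (r ≈ 0.92) drives three planted
  response classes — efflux-only (70% of variance), efflux-masked
  secondary (65% efflux + 13% from a genomic marker mutation invisible to
  the protein layer), and protein-marker drugs (50%) — plus null drugs.
  The masked class is what makes efflux correction reveal *additional*
  predictive models.
* **Missingness**: ~5% of cells overall, concentrated in ~15% of features
  (a third of their entries), because MS missingness is feature-driven;
  uniform 5% MCAR would leave almost no feature complete across 50 samples
  and would starve the no-missing-values feature selection.
* Intensities are 2^log2, masked, and row-scaled to mean 100 exactly.

What the generator does **not** emulate: peptide-level quantification
noise, TMT channel interference or batch structure, non-Gaussian abundance
distributions, correlated missingness with abundance, linkage between CNA
regions and complex membership, and any nonlinear genotype–abundance
relationship. Passing tests therefore demonstrate that each method recovers
the structure it targets under a faithful linear-Gaussian model at realistic
sizes and effect magnitudes — not that it is robust to every artefact of
real panels.

## Problem sizes and determinism

The test suite and the acceptance script run the full default cohort (2000
proteins) for network, subtype and coupling checks, and purpose-built
cohorts elsewhere: 1000 features for permutation-FDR calibration and
sensitivity (500 permutations, 20 null cohorts), 700 genes / ~20 variants
with 14–20 mutated lines for QTL replication (at 50 samples, BH thresholds
under 10⁴–10⁵ tests leave ~80% discovery power at the planted effect
sizes; the replication fixture is sized so the property being tested is the
method's, not the multiplicity's), and 24 drugs × 2 layers for the
drug-model census. Every stochastic step takes an explicit seed;
`generate_cohort` is byte-deterministic given its spec, permutation FDR
records its seed, and k-means/elastic-net randomness derives from the
passed seed.

## Known limitations

* The static tree cut needs a configurable height; very heterogeneous TOM
  scales may require adjusting it, where dynamic tree cutting would adapt.
* The pooled permutation null assumes exchangeable features after |t|
  standardization; strong per-feature variance heterogeneity with tiny
  groups could misestimate tails.
* PAC-based k selection inherits consensus clustering's preference for
  well-separated spherical classes; overlapping subtypes flatten the PAC
  drop and fall back to small k.
* Elastic-net feature attribution (nonzero coefficients) is reported from a
  full-data refit and is not a stable-selection procedure.
* GCT column metadata (GCT 1.3 beyond row annotations) is skipped with a
  warning; sample metadata travels separately.
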