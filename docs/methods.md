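# Methods

This note documents the models, numerical choices and limitations behind
`longicore`, in the order the discovery pipeline runs them.

## Synthetic cohorts

`longicore.synthetic.generate_abundance` emulates a 16S survey of a
long-lived cohort. The default design (135 samples, 2,000 OTUs, three
planted modules of 60/45/35 OTUs with nominal loadings 0.8/0.7/0.6, one
module linked to a binary longevity trait at correlation 0.5) mirrors the
scale of such studies while remaining fast to analyse.

**Latent factor model.** Each planted module m has a sample-level factor
f_m ~ N(0,1). Member OTU j gets a standardized log-scale profile
z_j = l_j f_m + √(1−l_j²) ε_j. Loadings decay linearly from the nominal
`latent_corr` down to 0.7·`latent_corr` across the block, so "the
strongest-coupled members" is well defined — these are the OTUs expected to
surface as network hubs. Background OTUs are independent noise.

**Binary trait.** The longevity flag is a median split of a Gaussian latent
correlated with the chosen module factor. A median split attenuates a
latent correlation ρ to ρ·√(2/π) on the binary scale, so the generator
inflates the latent correlation by 1/√(2/π); the *point-biserial*
correlation between flag and factor then lands at the requested
`trait_effect`. `trait_effect = 0` yields an independent balanced flag (the
null design used for calibration tests).

**Counts.** λ_j = b_j · exp(σ z_j − σ²/2) with σ = 1, counts ~ Poisson(λ)
(lognormal-Poisson), or Poisson-Gamma with dispersion φ for the
negative-binomial option (variance λ + φλ²). Two baseline regimes matter
and are deliberate:

* planted OTUs draw b_j log-uniformly in [20, 150] so the counting noise
  (var(log N) ≈ σ² + 1/λ) does not attenuate the designed correlations;
* background OTUs are mostly sparse (baseline −log u with u ~ U(0.6, 0.9),
  giving roughly 60–90 % zeros), but a 20 % subset draws a long-tailed
  abundant baseline in [10, 800]. This subset carries the bulk of each
  sample's total. Without it the planted blocks dominate the total and
  closure to relative abundance cancels their shared variation — an early
  version of the generator had exactly this defect, with observed
  correlations of ~0.15 for a designed ~0.45.

**Taxonomy.** Module OTUs cycle through a small set of genus names
(five per module by default); the trait module's genera are aliased to
Alistipes, Bacteroides, Blautia, Lachnospiraceae NK4A136 group and
Lactobacillus so recovery statements read naturally. Phyla are assigned so
Firmicutes/Bacteroidetes/Proteobacteria ratios are computable.

**What the generator does not emulate:** phylogenetic correlation between
related taxa, batch effects, variable sequencing depth beyond the Poisson
layer, and genuine compositional constraints (totals are sums of positive
parts, not fixed). Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and calibrated on data satisfying its own
assumptions — not that any particular real cohort will yield a clean
module.

Strain tables use one common "robustness" factor across the three
indicators plus indicator noise, mapped affinely to percentage scales; Ct
tables place the reference gene at a fixed baseline and shift the
treatment-group target Ct by −log2(fold).

## Network stage

Counts are closed to relative abundance and transformed with
log1p(10⁴ · rel) by default (Hellinger and identity transforms available);
the scale factor keeps small fractions from collapsing onto zero. MAD
filtering keeps the top half of OTUs (ties broken by column order,
deterministic). Adjacency, TOM and the scale-free fit follow the standard
weighted-network formulas; the fit index bins connectivity into 10
equal-width bins and regresses log₁₀ frequency on log₁₀ mean connectivity,
returning R² signed negatively for rising distributions. The soft threshold
is the smallest grid power reaching R² ≥ 0.85 (grid 1–10, 12–20), else the
best-fitting power. Note that a *bare* correlated block without background
has near-homogeneous connectivity and cannot reach a high scale-free R²;
the criterion is meaningful only on full tables with a sparse background.

**Dynamic branch cut.** Average-linkage trees of TOM dissimilarity grow
modules by accretion: a module's weakly-loaded members join one merge at a
time, so no single parent-child height gap marks the module boundary.
The cut therefore measures separation from the **core**: for every branch
with ≥ `min_module_size` (default 25) leaves, the height at which its first
`min_module_size` members assembled is recorded, and the branch qualifies
when (parent merge height − core height) exceeds a `deep_split`-scaled
fraction of the dendrogram height range (0.33/0.20/0.12/0.065/0.03 for
deep_split 0–4; default 3). Branches holding more than half of all leaves
are never modules (they are the background blob near the root). Among
nested qualifying branches the deepest win. Remaining elements are adopted
by the nearest module (average dissimilarity) when they sit within that
module's own spread — the PAM-like stage of the hybrid cut. Everything else
is grey. Module names come from a fixed colour vocabulary ordered by
decreasing size (ties by first-member position), so runs are comparable.

Eigengenes are unit-variance first principal components of the
standardized member submatrix (population σ), sign-oriented to correlate
non-negatively with the mean member profile; for the degenerate
anti-correlated-pair case the first member's loading is made positive
instead. Merging clusters eigengenes at dissimilarity 1 − cor and fuses
groups below 0.25, iterating to stability. Module–trait r uses Pearson
correlation with two-sided t p-values (n − 2 df); no multiple-testing
correction is applied to the module–trait screen (a Benjamini–Hochberg
column is reported alongside for inspection). GS and MM follow the usual
definitions; the MM–GS association within a module is computed on absolute
values.

A design caveat worth knowing: when a trait-linked module is abundant,
closure induces small *negative* trait correlations in the remaining
modules (compositional spillover). The planted module remains the
minimum-p module; the spillover is a property of relative-abundance data,
not a bug.

## Hubs and random forest

Module networks are exported density-controlled by default (top 3·|module|
edges by TOM weight) because no single absolute threshold suits all module
sizes; an absolute threshold mode exists. MNC is computed on the
thresholded, unweighted graph; hub ranking is (MNC desc, weighted
connectivity desc, id asc).

The random forest treats the binary labels as 0/1 and grows 500 bootstrap
regression trees of depth 7 with mtry = p/3, giving the two conventional
importance readouts: mean out-of-bag increase in squared error under
per-feature permutation, and total impurity (variance) decrease. The
bootstrap loop is explicit and seeded because per-tree out-of-bag indices
are needed for the permutation importance. Core genera are the
intersection of both top-10 importance lists with the top-10 hub genera,
reported in hub order. The intersection (not union) of the importance
lists is used; the union is easily obtained from the reported lists.

## Community statistics

Observed species, bias-corrected Chao1 (S_obs + F₁(F₁−1)/(2(F₂+1))),
Shannon (natural log by default, base configurable) and Gini-Simpson run
on raw counts; an optional without-replacement subsampling depth is
exposed but not applied by default, since diversity on raw versus rarefied
counts is a study-level choice. PERMANOVA partitions summed squared
distances into within/between components and permutes labels with a seeded
generator; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). Perfectly separated
groups give an infinite pseudo-F; a permutation that happens to reproduce
the separating partition ties it, so the theoretical minimum p is attained
only when groups are large enough that reproduction is improbable.

## Strain scoring and qPCR

KMO uses the inverse-correlation partial formula. For three indicators
driven by one factor the KMO ceiling is 0.8, not 1 (equicorrelation ρ → 1
drives the partials to 1/2); values above ~0.75 already indicate a
dominant factor at p = 3. PCA retains the smallest leading set of
components reaching 90 % cumulative explained variance; loadings are
eigenvectors scaled by √root with the largest-|loading| entry of each
component made positive, which fixes the otherwise arbitrary signs
deterministically. F_sum weights component scores by v_c/M using the
loadings as printed coefficient tables do; a loadings/√root
score-coefficient mode is available behind a flag. Standardization makes
the whole scoring affine-invariant in the raw indicators.

ΔΔCt centers each target's ΔCt on the control-group arithmetic mean
(median optional), so control fold changes have geometric mean exactly 1;
amplification efficiency is fixed at 2 with an efficiency-corrected mode
available.

## Problem sizes in the test and acceptance suites

The test suite exercises recovery at 120 samples × 400 OTUs over 12 seeds
(planted-module recovery ≥ 90 %), end-to-end core-genus recovery over 8
seeds (≥ 80 %), PERMANOVA calibration over 1,000 null simulations
(0.05 ± 0.02), TOM against a brute-force oracle on random 6×6 adjacencies,
and MNC against exhaustive component search on all 4- and 5-node graphs
plus random 8-node graphs. `scripts/acceptance.py` runs the larger
versions: 150 × 1,200 over 30 seeds and 135 × 800 over 10 seeds. These
sizes were chosen so the whole suite completes in well under a minute per
stage on a single CPU while leaving the statistical assertions
comfortably powered.

## Known limitations

* The dynamic cut cannot call a module that spans more than half of the
  filtered OTUs (it is indistinguishable from the background blob without
  external context).
* Module detection operates in memory on the full TOM; tables beyond a few
  tens of thousands of OTUs would need block-wise decomposition, which is
  out of scope.
* The scale-free criterion is diagnostic, not inferential; on tables
  without a sparse background the fallback (best-fitting power) governs.
* BIOM input is not supported; the on-disk interchange format is TSV with
  `#` comment headers throughout.
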