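# Methods

## Pocket definition and preprocessing

A binding pocket is ligand-defined: the set of complete residues (or
nucleotides) of the macromolecule with at least one heavy atom within a
cutoff distance of any heavy atom of the bound ligand. The default cutoff is
6 Å — the upper end of the 4–6 Å range conventional for protein–ligand
pocket definitions — and the distance test is **inclusive** (`d ≤ cutoff`);
the inequality convention is not universal, so it is fixed here and covered
by a test. An atom-level mode (individual heavy atoms within the cutoff,
without residue completion) exists for sensitivity analyses; it always
yields a subset of the residue-level cloud.

Before extraction, structures are cleaned to a homogeneous heavy-atom
representation:

- water (HOH/WAT/DOD) is removed;
- monoatomic ions are removed via a configurable residue-name list
  (default: NA, K, MG, CA, ZN, CL, MN, FE, NI, CU, CO, CD, BR, IOD).
  Polyatomic hetero groups (PO4, SO4, …) are retained by default: they are
  chemically ions but structurally part of the modeled environment, and the
  removal list is a parameter precisely because this boundary is a judgment
  call;
- hydrogen and deuterium atoms are removed unless `keep_hydrogens=True`;
- for atoms with alternate conformations, only the first listed conformer
  is kept;
- only the first model of multi-model (e.g. NMR) files is read.

Pocket *membership* is always decided on heavy atoms, in both hydrogen
modes; with `keep_hydrogens=True` the same residues are selected and their
hydrogens simply join the returned cloud. This makes the with-H/without-H
comparison a pure representation change, which is what a hydrogen
sensitivity analysis should isolate.

Residue numbering is taken verbatim from the source file (1-based,
insertion codes preserved). No protonation, structure repair, symmetry
expansion, or ligand-free cavity detection is attempted.

## Shape descriptors

For an N-atom cloud with centered coordinates rᵢ, the gyration tensor is
T = (1/N) Σ rᵢrᵢᵀ, all atoms weighted uniformly. The 1/N normalization
(rather than 1/(N−1)) leaves the eigenvalue ratios unchanged and makes
Rg² = λ₁+λ₂+λ₃ coincide with the mean squared distance to the centroid,
i.e. the standard radius of gyration.

Eigenvalues are computed with a symmetric eigensolver, sorted descending,
and negative round-off values (relative magnitude < 1e-12) clamped to zero.
Degenerate geometry is handled explicitly rather than rejected: N < 4 and
all-coincident clouds are errors (no 3-D shape exists); coplanar clouds get
λ₃ = 0; collinear clouds get λ₂ = 0 with `rEV32` defined as 0 and a
`collinear` flag. Ratios satisfy `rEV31 = rEV21·rEV32` exactly in exact
arithmetic; the implementation verifies this to 1e-9 on random clouds.

## Archetype partition

Thresholds are the sample medians of `rEV21` and `rEV32` over the pooled
two-group cohort (even counts: midpoint of the central order statistics).
Classification is the 2-level decision tree over the two independent ratios;
`rEV31` is deliberately excluded from assignment because it carries no
information beyond the product. The tie rule is **≥ median → "high"**: the
partition must be exhaustive and deterministic, the choice of side is
arbitrary, and it is documented and tested rather than left to float
comparison accidents. Each assignment records a `boundary_margin`
(min distance to either threshold); any perturbation smaller than the
margin provably cannot change the label.

## Bootstrap stability

Stability of the median-anchored partition is measured by a stratified
bootstrap: each replicate resamples every group with replacement at its
original size, refits the medians on the pooled resample, and classifies the
*resampled* pockets twice — under the replicate's thresholds and under the
reference thresholds. The adjusted Rand index and the fraction of
reclassified pockets between those two labelings isolate threshold
variability, which is the quantity of interest (the pockets themselves are
identical in both labelings). Alternative pairings (e.g. classifying the
original pockets under bootstrap thresholds) differ only in which points sit
near the thresholds; the chosen convention matches what the reported metrics
(threshold SDs, reclassification rate) describe. Randomness is a single
seeded generator consumed sequentially, so reports are bit-reproducible per
seed.

## Distances

Continuous similarity is the unweighted Euclidean distance on
(`rEV21`, `rEV32`, `rEV31`). The dependent third coordinate is included on
purpose: it spreads overall anisotropy into the metric without reweighting.
Block summaries over (archetype × group) cells use unordered distinct pairs
within a cell and all cross pairs between cells; self-pairs are never
counted and no centroid shortcut is used, so the full pair distribution is
what is summarized. The 5th percentile uses the linear-interpolation
quantile convention (numpy default).

## Statistical battery

- **Welch's t** (unequal variances, Welch–Satterthwaite df), computable from
  raw vectors or from (mean, SD, n) summaries so published summary tables
  can be consumed directly. SDs use the n−1 denominator throughout.
- **Cohen's d** with the pooled-SD denominator
  √(((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2)); at equal n this is √((s₁²+s₂²)/2).
  This denominator choice reproduces the published benchmark effect sizes
  exactly from their printed summaries, which is the deciding evidence for
  it. Direction is fixed group1 − group2 (RNA − protein when those labels
  are present).
- **Holm** (step-down, FWER) applied separately to the shape family
  {rEV21, rEV32, rEV31} and the size family {n_atoms, Rg}: shape and size
  answer different questions and are corrected as separate families.
- **Per-archetype MANOVA** on (rEV21, rEV32) with Pillai's trace
  V = tr(H(H+E)⁻¹) built from explicit between/within SSCP matrices, with
  the standard one-factor F approximation (for two groups: df₁ = p,
  df₂ = n − p − 1 via the general s/m/n' formulas). `rEV31` is excluded as
  algebraically dependent (it would make H+E singular). Univariate
  follow-ups use Welch tests with BH/FDR correction *within each archetype*
  (the correction family is per archetype: each archetype's follow-up is a
  separate question); size descriptors get Welch + Holm within each
  archetype. Box's M covariance-homogeneity statistic is reported as a
  diagnostic only — no automatic gate, since a failed homogeneity check
  changes interpretation, not arithmetic.
- **Chi-square of independence** on archetype × group counts, Pearson form
  without continuity correction, df = (r−1)(c−1).

Implementation leans on scipy/statsmodels/scikit-learn for the textbook
pieces (t tests, multiplicity corrections, chi-square, ARI); the MANOVA is
built from SSCP matrices directly and cross-checked against statsmodels in
the test suite.

## Synthetic data

The generators exist so every pipeline stage is testable without any
structure downloads.

- `sample_cloud` draws points with a prescribed population covariance
  spectrum, Gaussian or uniform-in-ellipsoid (bounded, like real pockets;
  semi-axes √(5σᵢ²) give the same covariance eigenvalues, so ratio targets
  are model-agnostic).
- `write_toy_complex` emits minimal, valid PDB files, each engineered to
  exercise one rule: the 6 Å complete-residue threshold, the cutoff sweep,
  first-altloc, first-model, and a hydrogen-sensitivity batch in which
  hydrogens are bonded ~1 Å from their parent heavy atoms and pockets have
  realistic (~90 heavy atom) sizes.
- `sample_cohort` draws per-pocket (rEV21, rEV32) around per-archetype
  centroids, sets rEV31 to the product, and attaches size descriptors and
  group labels. Its defaults are the benchmark study conditions: the
  published per-archetype combined ratio means/SDs, per-group size
  distributions, and per-group archetype counts (300 + 300 pockets).
  Sampled ratios are truncated to [0, 1] by clipping (default) or
  resampling.
- `sample_two_blob_cohort` builds the gap-separated stability fixture: one
  group per blob, so every stratified resample pools equal blob counts and
  all achievable medians fall in the gap, making perfect bootstrap
  stability provable by construction.

What the synthetic cohort does **not** emulate: real pockets have
correlated ratio/size descriptors, non-Gaussian and skewed spreads,
archetype-dependent covariance, and within-group structural redundancy.
Passing tests on synthetic cohorts therefore validate the *machinery*
(estimators, partition, bootstrap, test statistics) under the stated
conditions — they do not re-derive the empirical cohort-level numbers of
any real dataset, which require the underlying curated structures.

## Problem sizes and numerical choices

The test suite and acceptance script use: 10,000 random clouds for the
algebraic identities; 20 × 100,000-point Gaussian clouds for ratio
recovery (tolerance 0.02 absolute, ≈10 standard errors at that n); 101×101
classification grids × 25 threshold pairs against a brute-force oracle;
40-point distance matrices against an O(n²) loop (1e-12); 10,000 null
simulations at n = 30/group for Welch type-I calibration ([0.04, 0.06] band
at α = 0.05); and 1,000 bootstrap replicates on 600-pocket cohorts. Rigid-
motion invariance of ratios is checked to 1e-9 over 100 random rotations
and translations.

## Known limitations

- The extraction path handles single selected ligand instances; multi-copy
  ligands are iterated via `batch_extract`, and representative-chain
  deduplication (dataset curation) is out of scope.
- Inertia-based descriptors capture second moments only: no surface area,
  volume, branching, or local roughness, and no more than the four
  median-anchored classes.
- The chi-square and MANOVA assume independent pockets; structural
  redundancy within a cohort must be controlled upstream.
- Whether "ion removal" should extend to polyatomic ions is left as a
  configuration choice (see above); modified nucleotides receive no special
  treatment at extraction time.
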