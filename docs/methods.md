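# Methods

`mrsifp` implements an unsupervised analysis of 3D magnetic-resonance
spectroscopic imaging (MRSI) of gliomas: voxel spectra are decomposed into
a small set of non-negative metabolic sources, tumor voxels are selected
by metabolic indices, source-contribution profiles are embedded and
clustered to separate tumor subtypes, and per-patient metabolic
fingerprints are expressed as z-scores against matched healthy tissue.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Synthetic cohort model

No patient data ship with the package; a generator produces cohorts with
the statistical structure the analysis assumes.

**Spectra.** Each of nine metabolites (NAA, Cr, Cho, mI, Glu, Gln, 2HG,
Ser, Lac) is modelled as one-to-few Lorentzian lines at canonical 1H
chemical shifts (e.g. NAA 2.01 ppm, Cho 3.20, Lac 1.31, 2HG 2.25/4.02)
with a common 0.04 ppm FWHM, evaluated on an ascending 0.5–4.2 ppm grid
(512 points by default) and normalized to unit maximum. Full J-coupling
multiplets are deliberately not modelled: downstream decomposition needs
realistic overlap, not quantum-mechanical lineshapes. A voxel spectrum is
the concentration-weighted sum of basis spectra plus additive Gaussian
noise (SD 0.15 i.u.), rectified at zero to stay valid for non-negative
factorization; the clipped fraction is recorded.

**Cohort structure.** Defaults produce 12 patients — 5 astrocytoma (AC,
IDH-mutant), 5 oligodendroglioma (OG, IDH-mutant), 2 glioblastoma (GBM,
IDH-wildtype) — with per-patient tumor voxel counts drawn uniformly from
4–81 and healthy counts from 23–266. Tumor voxels occupy one hemisphere
of a 30×30×16 grid, healthy voxels the contralateral one.

**Concentrations.** Per-voxel true concentrations are log-normal around
subtype means (tumor CV 0.20, healthy CV 0.12), guaranteeing positivity
and the right skew seen in index histograms. The subtype means encode the
qualitative contrasts the indices rely on: both mIDH subtypes carry
substantial 2HG while GBM carries essentially none; all tumors have
elevated choline and depleted NAA relative to healthy tissue; AC is
myo-inositol-rich and OG serine-rich, so the two mIDH subtypes differ
multivariately rather than through any single metabolite (cystathionine,
an OG marker, is intentionally absent from the default basis and can be
added by the user). Reported "fitted" concentrations are the truth times
multiplicative log-normal error (CV 0.05).

**QC metadata.** FWHM, SNR and per-metabolite CRLB are drawn inside the
passing ranges; a configurable fraction of voxels (default 0.10) instead
violates exactly one rule, chosen uniformly among the three.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: acquisition physics (k-space, field
inhomogeneity, water/lipid residuals), spectral-fitting behaviour (the QC
metrics are sampled, not computed from the spectra), fitted baseline
signals, spatial correlation between neighbouring voxels, and partial
volume. Classification results on the synthetic cohort demonstrate that
the pipeline recovers planted structure, not that real gliomas are this
separable.

## Quality control and metabolic indices

Voxels pass QC iff FWHM < 0.15 ppm, SNR > 3 and every considered CRLB
< 20 % — all strict inequalities, with the CRLB rule restricted
(configurably) to the metabolites entering the indices. A separate
artifact rule flags a voxel when the maximum of its spectrum over a
signal-free baseline window exceeds that window's mean by more than 2.5
sample standard deviations (per voxel, ddof = 1). This rule is intended
for the smooth fitted-baseline signal produced by spectral-fitting
software; applied to a raw rectified noise floor, the max-over-window
statistic exceeds μ + 2.5σ for most voxels purely by extreme-value
behaviour of Gaussian noise. The pipeline therefore leaves the artifact
stage off by default for synthetic runs and enables it via configuration
for real data.

Tumor selection uses HGI = (2HG + Gln)/Glu (> 1.5, IDH-mutant patients)
and CNR = tCho/tNAA (> 0.4, wildtype patients); both ratios guard the
denominator with eps = 1e-9 and are invariant to common rescaling of a
voxel's concentrations. The rule is subtype-conditional because a
conjunction across both indices would exclude wildtype tumors, whose HGI
is low; the literal conjunction remains available (`rule="both"`).
Healthy tissue defaults to qc-passing, non-tumor voxels of the
contralateral hemisphere ("all non-tumor" is available). Quantiles use
type-7 linear interpolation.

## Non-negative matrix underapproximation

The decomposition solves, over non-negative W (m spectral points × r
sources, r = 7 by default) and H (r × n voxels),

    min ‖X − WH‖_F  subject to  W ≥ 0, H ≥ 0, WH ≤ X element-wise.

The underapproximation constraint forbids explaining more signal than was
observed anywhere, which drives the sources toward sparse, additive,
part-based spectra.

**Global solver.** Lagrangian relaxation: multipliers Λ ≥ 0 on the
violated constraints, HALS (hierarchical alternating least squares)
updates of (W, H) on the shifted data X − Λ, and the diminishing-step
multiplier update Λ ← max(0, Λ − (ρ/t)(X − WH)). Two implementation
choices proved necessary. First, an unconstrained HALS warm-up (one third
of the iteration budget) precedes multiplier activation: starting the dual
updates from a poor primal iterate lets early, large violations dominate Λ
and the diminishing steps never recover. Second, after every outer
iteration the current iterate is projected to exact feasibility (each
voxel's contribution vector is scaled by the largest factor ≤ 1 keeping
Wh ≤ x) and the best projected iterate is retained; the returned solution
is therefore exactly feasible and the reported objective sequence
non-increasing by construction. Initialization is NNDSVD (deterministic);
seeded random initialization is available. Sources are ordered by total
contribution and scaled to unit-maximum spectra, magnitudes carried in H.

**Rank one.** For r = 1 the constrained problem admits an exact feasible
alternating scheme: for fixed w the optimal h_j per voxel is the
least-squares coefficient clipped to the largest feasible value
(min_i x_ij / w_i over w_i > 0), and symmetrically for w. Each half-step
is an exact constrained minimizer, so iterates are always feasible and
the objective monotone. Because these fixed points sit against
feasibility walls, the solver multistarts deterministically (leading
singular vector, largest data columns, a flat spectrum, all binary
supports and 16 seeded random vectors when m ≤ 10) and, for small
problems (m ≤ 64), polishes the best candidates with a derivative-free
Powell search of the reduced objective w ↦ min_h ‖X − w hᵀ‖, seeded
additionally from a coarse grid when m ≤ 6. On hundreds of random 3×3 and
4×4 instances this matches or beats an exhaustive fine-grid search.

**Recursive mode.** Classical NMU deflation — rank-one fit, subtract,
repeat — is available behind a flag; it is valid because a feasible
rank-one fit leaves a non-negative residual.

**Downstream quantification.** Per-voxel source contributions are
re-estimated by non-negative least squares against the fixed W, uniformly
for tumor and healthy voxels (projecting tumor-derived sources onto
healthy tissue enables the tumor-vs-healthy fingerprints). Each source is
attributed to metabolites by NNLS unmixing against the basis; a
metabolite's share is its coefficient times its basis-spectrum integral,
normalized to 100 % per source.

## Embedding, clustering and scoring

Tumor-voxel contribution profiles are embedded in 2-D with UMAP
(n_neighbors 15, min_dist 0.1, Euclidean, fixed seed — none of these is
dictated by the procedure itself; all are configuration) under
leave-one-patient-out cross-validation: per fold, the per-source
z-standardization and the UMAP model are fitted on the other patients
only, and the held-out patient's voxels are transformed by the fitted
model, so no voxel is embedded by a model that saw its own patient.

Concatenating independently fitted fold embeddings is only meaningful up
to each fold's arbitrary layout. Two alignment steps bring every fold
into a common frame before its test embedding is retained: a global
Procrustes map (scale, rotation, reflection, translation) fitted on the
training voxels the fold shares with the accumulated reference, followed
by a local correction that displaces each point by the
inverse-distance-weighted mean residual of its 10 nearest anchors — the
local step reconciles per-cluster placement differences (small clusters,
such as a 2-patient subtype, can be positioned differently relative to
the large ones from fold to fold) that no single global map can absorb.
All anchors are training voxels of other patients, preserving the
leave-one-out guarantee. The reference frame accumulates each fold's
aligned layout so later folds always find anchors for every patient.

K-means (K = 3, k-means++, 10 restarts, fixed seed) clusters the
embedding; clusters map onto subtypes by Hungarian assignment on the
contingency table, making accuracy invariant to label permutation.
Accuracy and per-class recall/specificity carry percentile-bootstrap 95 %
CIs (2000 resamples over voxels). One-vs-rest ROC AUCs use
softmax-normalized negative distances to subtype centroids as continuous
scores, with midrank tie handling. Cluster quality is summarized by
silhouette, Davies-Bouldin and Calinski-Harabasz on the embedding
coordinates (NaN when fewer than two clusters exist). Feature importance
is the OLS coefficient matrix of the embedding coordinates on all
standardized source contributions jointly, with a logged small-ridge
fallback for rank-deficient designs.

## Fingerprints and group structure

For each patient and source, z = (mean tumor − mean healthy)/SD healthy
(sample SD; NaN when the healthy SD is zero; patients lacking healthy
voxels are excluded with a warning). The patients × sources matrix is
clustered by UPGMA (average linkage) on Euclidean distances;
missing cells use pairwise-complete distances rescaled to full
dimensionality rather than row deletion, preserving small-cohort rows.

By default each source column is standardized across patients before
distances are computed. Raw z columns can differ by orders of magnitude —
a source nearly absent in healthy tissue has a tiny healthy SD, so its z
values are huge and their sampling noise would dominate every distance;
unit-variance scaling lets each source contribute comparably, as is usual
before hierarchically clustering a heatmap. The scaling can be disabled
when the matrix scale is meaningful as given.

Between-group separation is reported two ways, since "inter-cluster
distance" admits several estimators: the mean pairwise distance between
members of the two groups, and the mean UPGMA cophenetic height. Within
groups, the mean per-source variance and the Shannon entropy of pooled
standardized profile values (64 equal-width bins by default) quantify
heterogeneity; entropy is bounded by log2(bins) and its magnitude is
bin-dependent, so the bin count is reported with the value. Entropy is
computed over patient-level profiles, matching its role as a measure of
case-to-case variability.

## Statistics

Kruskal-Wallis (tie-corrected, chi-square p), Welch's t (Satterthwaite
df), Mann-Whitney U (midranks, normal approximation), Levene (mean
centering by default, median = Brown-Forsythe optional) and Pearson
correlation wrap the scipy implementations with uniform result records;
Cohen's d uses the (n−1)-weighted pooled SD and is antisymmetric and
affine-invariant. Degenerate inputs resolve explicitly: identical data
give H = 0/p = 1; two zero-variance samples give p = 1 or 0 by mean
equality; constant input to Pearson or zero pooled SD for d yield NaN
with a warning. Group tests run on patient-level observations by default
— the 12 patients are the exchangeable units; voxel-level testing would
pseudo-replicate — with voxel-level use possible by passing voxel
samples. Raw p-values are reported; Benjamini-Hochberg adjustment is
available behind a flag. Under their nulls (n = 20 per group, 2000
simulations) each test's type-I error at α = 0.05 falls within
[0.03, 0.07].

## Problem sizes and determinism

The shipped analyses use the default cohort (~1900 voxels, 512 spectral
points, rank 7), 500-voxel/256-point planted-source instances at SNR 20,
and 3×3/4×4 instances for oracle comparisons; the full pipeline runs in
well under a minute per seed on one CPU, and seed-averaged evaluations
use 5 seeds. Every stochastic component (generator, solver
initialization, UMAP, K-means, bootstrap) takes an explicit seed; a
pipeline rerun with the same configuration and seed reproduces
byte-identical outputs, verified by manifest checksums.

## Known limitations

- The artifact rule cannot be exercised end-to-end on synthetic data
  (no fitted-baseline model); it is unit-tested against its definition.
- Fold-to-fold embedding alignment assumes the underlying cluster
  structure is stable across folds; with classes represented by a single
  patient the local correction has no same-class anchors and reduces to
  the global map.
- Source attribution shares the basis-set limitation of spectral fitting
  (unknown metabolites are attributed to the nearest known ones); the
  decomposition itself does not.
- The entropy and inter-group distance magnitudes depend on binning and
  scaling conventions and are comparable only within a fixed
  configuration.
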