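# Methods

## Model and procedure

The package decomposes per-subject connectivity matrices of two kinds into
a common set of gray-matter spatial sources.

**Functional branch.** For one subject, voxel time courses are
standardized (mean 0, sample sd 1, n−1 denominator; constant voxels are
zeroed, kept in the mask, and reported — dropping them would break voxel
alignment across subjects).  The functional connectivity matrix is the
voxel-pair sample correlation `C = X̃′X̃/(T−1)`.  It is never materialized:
the SVD `X̃ = Ṽ Σ̃ Ũ′` yields the identical spatial eigenstructure, and for
a demixing matrix `W` estimated on the top-c spatial singular vectors,

    S = W Ũ′,   R = Ũ Σ̃² W⁻¹/(T−1)   ⇒   R·S = rank-c truncation of C,

an identity the test suite checks to 1e-6 relative Frobenius error and
that holds to machine precision in practice.  The placement of the
1/(T−1) factor is the only reading under which `R·S` reproduces the
correlation matrix; it is fixed here as part of the package contract.

**Structural branch.** The gray × white fiber-count matrix gets the same
truncated SVD (optionally after an elementwise `log1p`; the default is no
transform, with `log1p` offered because streamline counts are heavy-
tailed).  Sources live on the gray side, connectivity maps on the white
side: `R = V̄ Σ̄ W⁻¹` reproduces the transposed count matrix at rank c.

**Joint decomposition.** Two reduction stages per modality:

1. *Subject level.* Truncated SVD at order `subject_r`.  This is the only
   stage at which variance ordering acts, because the second stage
   consumes the *whitened* subject bases `ũ_k′` (orthonormal rows).  The
   choice of whitened stacking is deliberate: it is the convention under
   which the group back-reconstruction formula below is exact.
2. *Group level.* The stacked subject bases get a second truncated SVD at
   order `m` per modality, recording each subject's partition `Ṽ_k` of
   the co-basis.

The two group bases are *balanced* — each block scaled to exactly unit
row power (`sqrt(V_gm − 1) · Ũ_mod′`) — and stacked into a
`(m_FC + m_SC) × V_gm` matrix, so neither modality dominates the
decomposition through raw variance.  Because shared sources make the two
blocks mutually correlated, the stack is then jointly whitened; the
whitening matrix is folded into the stored demixing matrix so all
reported algebra refers to the unwhitened concatenation.

Spatial ICA on this matrix produces the aggregate shared sources.
Subject- and modality-specific maps follow the group-ICA
back-reconstruction chain

    Ũ_k′ = N · Σ̃⁻¹ Ṽ_k′ ũ_k′
    S_k  = W[:, block] · scale · Ũ_k′
    R_k  = ũ_k σ̃_k^p Ṽ_k Σ̃ A[block, :] / (scale · norm)

with `p = 2, norm = T−1` (functional) or `p = 1, norm = 1` (structural)
and `A = W⁻¹`.  Two contracts define correctness: the subject mean of
`S_k` equals the aggregate sources' modality contribution (an exact
algebraic identity of this chain, verified at ~1e-15), and `R_k·S_k`
approximates the subject's connectivity matrix no worse than 1.05× the
subject's own PCA-truncation floor (observed ratios ≈ 1.00–1.03 on the
reference cohort).  The printed form of the back-reconstruction involves
an inverse of the non-square `Ṽ_k`; the `N Σ̃⁻¹ Ṽ_k′` chain is the
standard pseudo-inverse resolution and is what makes the mean-consistency
contract exact.

## ICA engine

The default separator is Infomax: batch natural-gradient updates with the
logistic score, `W ← W + lr (I − tanh(Y/2) Y′/n) W`, learning rate
annealed when a step grows, re-orthonormalized each step, stopping when
the weight change drops below `tol` (default 1e-7, cap 2500 iterations).
After convergence `W` is replaced by its polar (closest-orthogonal)
factor: on whitened input the true unmixing is orthogonal and Infomax's
estimate differs from it only by a per-row scale, which the polar factor
removes exactly.  Source rows are therefore exactly uncorrelated with
unit power, and each is oriented so its largest-magnitude value is
positive (determinism across platforms).  A deflationary FastICA
(scikit-learn, logcosh) sits behind `algorithm="fastica"`; it also
handles sub-Gaussian sources, which plain logistic Infomax cannot and
which this package deliberately does not extend to.  `algorithm="identity"`
bypasses separation for algebraic tests.

**Stability (ICASSO).** ICA is rerun `n_runs` times (default 20) with
seeds `base_seed + i`.  All component estimates are pooled and clustered
by absolute spatial similarity with single linkage (the minimum-spanning-
tree agglomeration) into c clusters.  Cluster quality is average
intra-cluster similarity minus average similarity to non-members, clipped
to [0, 1].  Similarity is the absolute *uncentered* correlation (cosine);
source maps are zero-mean to numerical precision, and the uncentered form
together with exactly-orthogonal source rows makes the degenerate
identical-runs configuration yield quality exactly 1.0 rather than
approximately (values within 1e-12 of 0 or 1 are snapped).  The best run
maximizes the summed similarity of its components to the cluster
centrotypes, ties broken by lowest run index.

## Feature selection and reporting

Components are sorted by mean explained variance, computed per modality
as the squared column norm of the mixing matrix restricted to that
modality's block (sources have unit variance, so column power is variance
share); "loadings" throughout means columns of `A = W⁻¹` partitioned by
block, averaged as unweighted absolute values — the literal reading of
the contribution-ratio recipe.  A component is *shared* when its FC
contribution lies in [0.2, 0.8], bounds inclusive.  Artifact screening is
a manual exclude-list only; no automated classifier is offered because no
defensible criteria exist at this scale.

t-statistic maps are one-sample t across subjects (`mean/(sd/√n)`,
zero-variance voxels flagged and set to 0).  Thresholding retains values
above the map's own `μ + kσ` with k = 3 for source maps and k = 2 for
connectivity maps; the μ+3σ ROI is always a subset of the μ+2σ ROI.
Atlas labeling uses containment overlap — `100·|ROI ∩ label|/|ROI|` — not
Dice, because a tract ROI must be nameable even when the best atlas match
covers only a few percent of it; the best label is the containment
argmax, ties to the lowest label id, and an ROI touching only background
is "unlabeled".

## Synthetic cohorts

The generator plants compact spherical gray-matter sources (fixed radius
1.6 voxels, Gaussian interior profile, strictly disjoint support) and
expresses them in two modalities.  Functionally, each subject's time
series is a sum of rank-1 source × latent-course terms plus white noise;
latent courses are i.i.d. unit Gaussians, so the implied correlation
matrix is exactly the sum of outer products the model assumes.  Each
functional map is the source blob plus a 0.3-weighted smaller partner
blob (radius 1.2) — a weaker secondary network node.  The partner must be
smaller than the source: with equal masses the expression map itself
would correlate with the source at only ~0.96, making the source
unrecoverable at high fidelity by construction.  Structurally, fiber
counts are Poisson around `mean_count · strength · S ⊗ B` where `B` are
elongated tract-like cylinders in the white-matter grid, placed by a
shuffled systematic search with at most 10% pairwise voxel overlap —
freely overlapping tracts make structural maps near-collinear and destroy
the identifiability of the structural side.

Default study conditions: 4 shared + 2 FC-only + 2 SC-only sources on a
12×12×6 gray / 10×10×6 white grid, 10 subjects, 300 timepoints, noise sd
0.5 (SNR ≈ 2 at blob cores), mean count 20.  Shared sources have base
strength 1.0 and modality-specific sources 0.7, with per-subject
multiplicative jitter U(0.9, 1.1): shared sources are modeled as the
dominant connectivity modes, which is what makes symmetric model orders
sized to the shared subspace (the convention used here, mirroring the
practice of setting the order to the number of reliable sources)
well-posed — subject-level PCA orders by variance, and without the
strength gap the truncation would be rotation-degenerate.

What the generator does **not** emulate: hemodynamics, physiological and
motion artifacts, spatial autocorrelation of noise, realistic tract
geometry, and between-subject anatomical variability.  Passing tests
therefore demonstrate the correctness of the algebra, the estimator, and
the selection logic under the stated generative law — not performance on
real MRI data.

## Numerical choices and problem sizes

- Sample statistics use the n−1 denominator everywhere.
- Whiteness and row-variance conventions are uncentered (second moments
  about zero): the PCA-chain algebra is exact under this convention and
  spatial basis rows are near-zero-mean anyway.
- Spatial basis columns are sign-fixed (largest-magnitude entry positive)
  at every SVD, making the whole pipeline bit-reproducible for a given
  master seed; all randomness derives from that one seed.
- Rank-deficient inputs fail fast: joint whitening refuses Gram matrices
  with eigenvalue ratio below 1e-10, and degenerate (all-zero) modalities
  are rejected before concatenation.
- Test and acceptance problem sizes (hundreds of voxels, tens of
  subjects, order ≤ 12) are chosen so the full suite and the acceptance
  script each run in minutes on one CPU; they are scaled-down analogues
  of the method's intended regime, not performance benchmarks.

## Known limitations

- Subject-level back-reconstructed maps are group-informed estimates and
  carry substantial shrinkage/noise at the default conditions (single-
  subject functional R maps correlate ~0.75–0.85 with their generative
  oracle, versus >0.98 for group averages); single-subject inference is
  out of scope.
- Functional R maps live on the correlation scale and saturate: they are
  seed-based correlation maps of the source ROI, not amplitude maps of
  the underlying mixing.
- Logistic Infomax assumes super-Gaussian (sparse) sources; use the
  FastICA engine for sub-Gaussian structure.
- No automatic model-order estimation: orders are caller-chosen, with the
  symmetric two-modality convention as the default.
- Grid matching between modalities (resampling/registration) is assumed
  done upstream; masks of both modalities must already live on their
  final grids.
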