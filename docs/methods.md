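# Methods

## Signal model and estimators

A voxel is described by a diffusion tensor D (carried in units of
10⁻³ mm²/s throughout the package) and a fully symmetric rank-4 kurtosis
tensor W normalized against MD² (the standard DKI convention):

    ln S(b, n) = ln S₀ − b·(nᵀDn) + (1/6)·b²·MD²·W(n),
    MD = tr(D)/3,   W(n) = Σ W_ijlm n_i n_j n_l n_m.

The 1-3-9 acquisition (1 × b = 0; x, y, z at b₁ = 1000 s/mm²; nine
directions at b₂ = 2500 s/mm²) determines the two rotation invariants in
closed form:

- **Axis diffusivity / MD.** Along a fixed direction, h(b) = ln S/S₀ is
  exactly quadratic in b, so the two shells give
  D = (b₁²h₂ − b₂²h₁)/(b₁b₂(b₂−b₁)) per axis and MD = (Dxx+Dyy+Dzz)/3. The
  quadratic coefficient V = MD²·W(axis) is exposed as a diagnostic.
- **MKT.** The default nine directions are the three axes plus the six
  axis-pair bisectors (e_i ± e_j)/√2, with weights 1/15 (axes) and 2/15
  (bisectors). These weights solve the degree-4 moment conditions exactly:
  the weighted second moment is I/3 and the weighted fourth moment is the
  isotropic fourth-moment tensor. Consequently the weighted mean of the
  high-shell log-attenuations satisfies h̄₂ = −b₂MD + (1/6)(b₂MD)²·MKT with
  MKT = tr(W)/5 exactly, giving MKT = 6(h̄₂ + b₂MD)/(b₂MD)². On noise-free
  data both estimators are exact to machine precision for arbitrary
  anisotropic (D, W); the test suite verifies this against an independent
  dense 60-direction, 3-shell, 21-parameter least-squares fit.

The direction set is one valid realization of a degree-4 spherical
quadrature containing the coordinate axes; `quadrature_weights` computes
exact non-negative weights for alternative direction sets by constrained
least squares (non-negative least squares on the moment conditions) and
raises rather than returning an inexact set (e.g. for coplanar directions).

## Noise model, Rice-floor correction and noise-aware fitting

Magnitude MRI noise is Rician: M = |A + ε₁ + iε₂| with ε ~ N(0, σ²). The
noise scale σ is estimated from the b0 background (outside the dilated
brain mask) via the Rayleigh mean, σ̂ = mean(M)/√(π/2), or supplied
explicitly. The Rice-floor step is the closed-form second-moment
correction S = √(max(M² − 2σ², 0)), which is exactly unbiased in the power
domain (E[M²] = A² + 2σ²). Its amplitude-domain bias is *not* smaller than
the raw magnitude's for A/σ ≲ 8 (the Jensen effect of the square root
roughly mirrors the Rice floor), which is why the correction's guarantee —
and the corresponding test — is stated on powers, not amplitudes.

Plain log-attenuations of noisy amplitudes carry a first-order Jensen bias
(E[ln M] < ln A) that propagates into MKT roughly as −6σ²/(A²(b₂MD)²) per
direction; at SNR 50 this depresses MKT class means by 0.02–0.03, an order
of magnitude above the recovery tolerances. The fit therefore applies two
noise-aware refinements whenever a noise level is known (σ > 0 propagated
by preprocessing):

1. **Exact Rician log-moment inversion.** M²/σ² follows a noncentral
   chi-square with 2 degrees of freedom and noncentrality λ = A²/σ². Its
   exact log-expectation φ(λ) = E[ln χ′²₂(λ)] = ln 2 + E_{J~Poi(λ/2)}[ψ(1+J)]
   is tabulated once (Poisson–digamma series up to λ = 2000, third-order
   central-moment expansion beyond; the splice agrees to <1e-6) and the
   log-amplitude is estimated by inverting it: ln Â = ½ ln(σ²·φ⁻¹(ln M²/σ²)).
   The remap is monotone, finite down to the noise floor, and removes the
   first-order log bias without the noise-conditioned voxel selection a
   hard SNR threshold would introduce.
2. **Delta-method MKT compensation.** MKT = g(h̄₂, u), u = b₂MD·10⁻³, is
   nonlinear in the noisy MD in its denominator. Both h̄₂ and MD are linear
   forms in the per-volume log-amplitudes, whose variances are
   approximately σ²/A² + σ⁴/A⁴ (plug-in 1/λ̂), so the second-order bias
   ½·g_uu·Var(u) + g_{h̄u}·Cov(h̄₂, u) is evaluated per voxel and
   subtracted. The u⁻³/u⁻⁴ factors are themselves evaluated at the noisy u,
   which would inflate the compensation by (1+6q) resp. (1+10q) with
   q = Var(u)/u²; the implementation deflates by exactly these factors and
   clips the total compensation to ±2 for numerical safety.

With σ = 0 both refinements are inactive and the fit is the pure closed
form (noise-free pipelines reproduce ground truth to ≤1e-10). Measured on
uniform phantoms at SNR 50, the residual per-voxel MKT bias is ≤0.001 for
MD in 0.6–1.4 ×10⁻³ mm²/s and ≤0.004 out to MD = 2.0.

**Known limitation.** For voxels with b₂·MD ≲ 1 (MD ≲ 0.4 ×10⁻³ mm²/s at
b₂ = 2500) the kurtosis contrast (1/6)(b₂MD)²·MKT falls below the log-noise
at SNR 50; per-voxel MKT there has a standard deviation of 0.3–1 and the
finite QC window necessarily truncates its noise distribution
asymmetrically. Lesion classes whose generating MD distribution reaches
that region (FLAIR-L, BH, with MD floors at 0.1) retain a positive
class-mean MKT bias of roughly +0.01 that no per-voxel estimator can
remove at this SNR.

Denoising and Gibbs-unringing are declared hook points that default to
pass-through: their algorithms belong to cited external work and the
synthetic data contains neither artifact. The preprocessing order is
denoise → Gibbs → Rice floor, with every applied step logged.

## Quality control

Voxels are flagged (never clipped) when any signal is non-positive, any
diffusion-weighted signal reaches S₀, or the estimates leave the physical
windows MD ∈ (0, 3.0] ×10⁻³ mm²/s, MKT ∈ [−0.5, 3.0] (configurable via
`QCBounds`). Downstream per-lesion means use QC-valid voxels only;
components with no valid voxel are dropped with a logged warning.

## Lesion analysis

Lesions are connected components under 26-connectivity (configurable to 6
or 18), labeled deterministically by the lexicographically smallest voxel
of each component. CE-L and BH masks are subtracted from the FLAIR-L mask
before labeling (they are FLAIR-hyperintense too), and FLAIR-L components
smaller than 10 voxels are excluded — "smaller than" read strictly, so a
10-voxel lesion survives. Rater agreement utilities (voxelwise consensus
product, Dice coefficient) operate on binary masks on a shared grid. The
unit of all statistics is the per-lesion/per-ROI mean of MD and MKT.

## Group statistics

Kruskal–Wallis (tie-corrected, χ² reference with k−1 df) and Dunn's z-based
pairwise tests with the tie term Σ(t³−t) and Bonferroni adjustment
min(1, m·p) over all C(k,2) pairs; both validated against exhaustive
relabeling with independently coded rank formulas. The non-enhancing group
(NE-L) is the concatenation of FLAIR-L and BH, so its mean is the
size-weighted mean of the two group means exactly. Pearson correlations use
the product-moment estimator with the t-based two-sided p-value.

The lesion-category model is a multinomial logit (maximum likelihood,
Newton) over {NAWM, CE-L, BH} against the FLAIR-L reference, with MKT and
MD (native 10⁻³ mm²/s units) as predictors and age, disease duration, EDSS
and lesion size as covariates. Because several lesions share a patient, the
default covariance is the cluster-robust sandwich with per-patient score
sums; with singleton clusters it reduces to the heteroskedasticity-robust
covariance (verified in tests), and a naive-ML option exists for
comparison. Non-convergence and diverging coefficients raise a separation
error naming the offending predictor. The ×100 MD factor is applied only in
display layers; stored values stay in native units.

## Synthetic cohort

The generator emulates a single-center study on one co-registered
98³ grid of 2 mm isotropic voxels: 37 patients and 11 controls, a spherical
"brain" of radius 40 voxels, S₀ = 1 and SNR 50 at b0 (σ = 0.02), the
clinical 3 T regime where the Rice-floor machinery is genuinely exercised.
Per category the true (MD, MKT) pairs are drawn from a bivariate normal
(means, SDs and MK–MD correlation from the packaged per-class fixtures)
truncated at ±3 SD and at the physical floors MD > 0.1, MKT > 0.05 — the
printed mean ± SD summaries say nothing about distribution shape, so the
truncated normal is a documented assumption. Parameters are constant within
a component, making the per-lesion acceptance surface exact, and tissue is
isotropic per voxel (the analysis uses only the two rotation invariants; an
anisotropy switch exists in the model type for estimator stress tests
only). Lesions are random axis-aligned ellipsoids (semi-axes 1.5–2.8 voxels
for FLAIR-L/BH, guaranteeing ≥19 voxels and hence the ≥10-voxel floor;
1.8–3.2 for CE-L), ROIs are spheres of radius 2.5 voxels, six per subject;
components are placed with at least a one-voxel gap by reserving dilated
bounding boxes, so labeling recovers exactly the generated components.
Cohort-wide lesion totals (30 CE-L over 11 carrier patients, 832 FLAIR-L,
667 BH) are partitioned across patients multinomially with exact totals.
Covariates are scaled-beta draws matched to the emulated population (age
18.6–64.9 y, median ≈36; duration 4–22 y, mean ≈6; EDSS 0–5.5 in 0.5
steps, median ≈2); they matter only as regression covariates. All
randomness flows from per-purpose child streams of the single cohort seed,
so the entire cohort — masks, values, noise, covariates — is a pure
function of (CohortSpec, seed).

What the generator does **not** emulate: brain anatomy, partial-volume
mixing at mask borders, Gibbs ringing, motion/eddy artifacts, registration
error (everything shares one grid), spatial noise correlation, or
within-lesion heterogeneity. Passing recovery tests therefore demonstrate
correctness of the estimation and statistics chain under the stated noise
model, not robustness to acquisition artifacts that the out-of-scope
preprocessing steps (denoising, Gibbs unringing, eddy/motion correction,
registration) would address on real data.

## Problem sizes and determinism

The default cohort (48 subjects × 98³ × 13 volumes at SNR 50) generates,
fits and analyzes in about 90 s on one CPU; smoke configurations use 2–3
subjects on a 64³ grid with lesion totals scaled in proportion to the
patient count, preserving the per-patient burden. All estimators are pure
closed forms with no iterative fitting or hidden random state; repeated
runs are bit-identical given the same spec.
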