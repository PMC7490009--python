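# Methods

## Scope and model

The package quantifies translation at single-mRNA resolution from fixed-cell
two-channel 3D fluorescence stacks: an smFISH mRNA channel and a SunTag
(scFv–sfGFP) protein channel.  The measurement chain is

1. detect diffraction-limited spots independently per channel;
2. calibrate the intensity of one released, fully synthesized SunTag array
   (`I_single`, the "idealized single peptide") from cytoplasmic protein
   spots away from every mRNA;
3. quantify each mRNA's translation site by a constrained Gaussian fit near
   the mRNA and express it in peptide units, `N = I_ts / I_single`;
4. classify each mRNA as associated with SunTag signal iff `N ≥ 1`,
   aggregate per cell, filter cells by mRNA count, and compare conditions.

Because the source study deposits no raw images, all pipeline validation
runs on synthetic scenes whose generating parameters are known exactly; the
per-condition translating probabilities are the study conditions themselves
(0.63, 0.03, 0.05, 0.50 for untreated, puromycin, emetine + puromycin, and
anisomycin + puromycin).

## Synthetic scenes

**Geometry.** 11 × 256 × 256 voxels by default, 107.5 nm x-y pixels and
300 nm z-steps; an elliptical cell with a central elliptical nucleus,
masks extruded in z.  The default stack size keeps a 4-condition, 24-cell
experiment at desk scale (a few minutes on one CPU) while holding 8–30
well-separated mRNAs per cell.

**Scene statistics.** Each of `n_mRNA ~ Uniform{8..30}` mRNAs is placed
uniformly over the cytoplasm (z in [2, n_z−3] so fits are never clipped at
the axial boundary) with a minimum pairwise x-y spacing of 5 px — enforced
among all emitters, because the quantification (like any single-site
Gaussian fit) cannot disambiguate overlapping sites.  An mRNA is
translating with probability `p_translating`; translating mRNAs carry
`k = 1 + Poisson(λ=4)` nascent chains.  The study never states ribosome
load per translating mRNA; λ = 4 puts essentially all translating sites
above the 1-peptide threshold (P(k = 1) ≈ 1.8%), so the estimator's target
equals `p_translating`.  Free single peptides arrive as
`Poisson(20)` per cell at exactly 1.0 single-peptide unit each (released
arrays are fully synthesized and hence equal in length); 20 per cell keeps
calibration comfortably above its 5-spot minimum.  mRNA-channel intensities
are log-normal with mean 2000 counts and CV 0.2 (no intensity model is
stated for the mRNA channel; single hybridized transcripts have modest
brightness spread).

**Optics and camera.** Spots render as point-sampled anisotropic 3D
Gaussians, σ_xy = 100 nm, σ_z = 350 nm — consistent with a high-NA
spinning-disk system at GFP emission — truncated at 4σ (≥ 99.98% of the
mass).  At these widths (≥ 0.93 voxels) the discrete sum of the Gaussian
equals its integral to better than 1e-6 relative, so integrated intensities
are conserved from ground truth through rendering to fitting.  The camera
adds a 100-count offset, Poisson shot noise through a unit gain, and
2-count Gaussian read noise; gain = 0 and read noise = 0 give bit-exact
deterministic renders for tests.  Default single-peptide integrated
intensity is 1200 counts (peak amplitude ≈ 75 counts, ≈ 7.5× the shot-noise
standard deviation of the background), a realistic regime where single
peptides are individually detectable but not noise-free.

**What the simulator does not emulate** — and therefore what passing tests
do not establish about real data: optical aberrations and PSF asymmetry,
photobleaching, nuclear mRNA, cytoplasmic autofluorescence structure,
cell-to-cell background variation, touching cells, and segmentation error
(masks are inputs).  Recovery of the preset fractions shows the estimator
chain is unbiased under the stated model, not that detection thresholds
transfer to any particular microscope.

## Detection and fitting

Candidates are 3×3×3 local maxima of a sign-flipped Laplacian-of-Gaussian
response at the PSF scale, above `median + k_mad·(1.4826·MAD)` of the
response (k_mad = 6, i.e. six robustly-estimated standard deviations — at
the default noise this gives no false maxima on spot-free stacks) and above
1e-3 of the global maximum (guards the noiseless case, where the MAD is
zero and float ripple is the only texture).  Ties break lexicographically
on (z, y, x).

Each candidate seeds a trust-region least-squares fit of
`A·exp(−(Δx²+Δy²)/2σ_xy² − Δz²/2σ_z²) + B` over a 5 × 11 × 11 window
(matching the 11 × 11 x-y box with the anisotropic z-sampling), clamped at
stack edges.  A fit fails when it does not converge, `A ≤ 0`, the center
leaves the clamped window, or a σ pins at its bound (0.2–6 voxels) — the
last is what rejects flat/noise-only windows.  Sub-voxel localization is a
by-product; intensity accuracy is what the downstream statistic needs.
Accepted spots must pass amplitude/width bounds (defaults 0.3–3 voxels
σ_xy, 0.3–4 voxels σ_z), and duplicate fits within 2 px of a brighter
accepted spot collapse to one emitter.

## Calibration and site quantification

Free peptides are protein spots inside the cytoplasm mask farther than
300 nm (x-y) from every detected mRNA.  Spots outside median ± 3·MAD in
integrated intensity or in either σ are dropped — an automated stand-in for
the by-eye curation such data normally receive — and `I_single` is the
*mean* intensity of the survivors (an average, not a median, because the
unit is defined as the averaged single-peptide image).  Calibration is
per cell and needs ≥ 5 surviving spots, else the cell is reported as a
calibration failure and skipped.

Site quantification searches the brightest voxel in the 11 × 11 x-y box
around the mRNA within ±2 z-planes of the mRNA's plane (the box is stated
in 2D only; ±2 planes ≈ ±600 nm covers σ_z ≈ 1.2 z-steps), fits a Gaussian
there, and keeps the site only if the fit passed, its σs lie within
0.5–3× the calibration medians, and its center is within 3 x-y px
(~320 nm) of the mRNA — distance and shape filters are stated in the
procedure without values; these defaults are the package's choices.  Any
failure sets `I_ts = 0`, so `N = 0` and the mRNA counts as unassociated,
matching the convention that unfittable sites carry intensity zero.  Site
intensity is integrated in 3D for consistency with the free-peptide unit.

## Statistics

Per cell: fraction = associated / total cytoplasmic mRNAs; cells contribute
iff `6 ≤ n_mRNA ≤ 35` ("more than five and fewer than 36"; the alternative
"fewer than 35" phrasing elsewhere in the source is noted and not adopted).
Conditions summarize as mean ± SEM over included cells.  Pairwise
comparisons use the two-sided Welch t-test by default (the t-test variant
is unstated; unequal variances is the safer default, and a pooled-variance
flag exists).  No multiple-testing correction is applied, matching the
presentation of individual pairwise tests.  Degenerate inputs are explicit:
both samples constant and equal gives t = 0, p = 1; constant and unequal
raises.

## ROI quantification

Average-intensity projection (per-pixel mean over z), then the mean over
pixels whose centers fall inside a polygonal ROI under the even-odd rule
(pixel (j, i) center at (i + 0.5, j + 0.5); sub-pixel handling is not
specified by the original ImageJ workflow, and center-containment is the
simplest reproducible rule).  Values normalize to the control-group mean,
so the control group averages to exactly 1 and global exposure changes
cancel.  No background subtraction precedes the measurement (none is
stated).  ROIs are inputs; the mitotic zone is not segmented automatically.

## Diffusion

`rms_displacement` returns `sqrt(2nDt)` and `time_to_reach` returns
`x²/(2nD)`, exact inverses; D defaults to 126 µm²/s (cytosolic GFP).  With
n = 1, displacement reaches 100 µm at t = 39.68 s < 60 s, the spatial-
resolution bound on short puromycin labeling.

## Determinism and problem sizes

The experiment is a pure function of (config, master seed): per-cell seeds
are SHA-256 hashes of (master seed, condition, cell index), so adding cells
or conditions never perturbs existing ones, and identical configs reproduce
byte-identical tables.  The shipped analysis and the acceptance script use
24 cells per condition at 11 × 256 × 256 voxels — the scale of the original
experiment (20–27 cells per condition) — which makes the binomial
cell-to-cell spread, not pipeline error, the dominant uncertainty in the
recovered mean fractions (SEM ≈ 1–2 percentage points).

## Known limitations

- Dense fields: the fitter is single-emitter; sites closer than ~3 px are
  not disambiguated (the generator's spacing constraint makes this explicit
  rather than hiding it).
- `I_single` inherits any fit-model mismatch (e.g. a slightly non-Gaussian
  PSF) multiplicatively; on real data this cancels in `N` only to the
  extent that sites and free peptides share a PSF.
- The per-cell calibration needs enough free peptides; sparse cells fall
  back to nothing rather than borrowing a condition-wide unit (a possible
  extension).
- The association threshold at exactly one peptide unit makes k = 1 sites
  a coin flip under noise; with the default load distribution such sites
  are ≈ 1.8% of translating mRNAs, so the induced bias is negligible, but
  quantifying low-load biology would need a different threshold rule.
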