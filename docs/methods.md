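# Methods

## Imaging model

The pipeline treats a CT acquisition as a linear, shift-invariant blur: the
true density field is convolved with a Gaussian point spread function (PSF)
whose width σ is specific to the scanner and reconstruction kernel, box
averaged over the slice thickness along z, sampled onto the HR-QCT voxel
grid, and corrupted by additive white Gaussian noise in calibrated units
(mgCaHA/cc). The scanner presets are σ = 0.39 mm (Siemens, B70s kernel,
1.00 mm slices), 0.61 mm (Philips, D kernel, 1.00 mm) and 0.55 mm (GE, BONE
kernel, 1.25 mm); the preset values are interpreted as Gaussian σ in mm and
applied both in-plane and along z, with the slice-thickness box average
dominating axial resolution. Correlated CT noise, beam hardening and ring
artifacts are not modeled. The box average is the simplest slice-profile
model consistent with CT reconstruction; nothing downstream depends on its
exact shape because the analysis direction is in-plane.

## The phantom forge

Phantoms are elliptic cylinders: a periosteal ellipse (default semi-axes
9 × 7 mm, height 12 mm — a deliberately scaled-down vertebral body chosen
so a full cohort simulates in minutes; a real T12 is ~40 × 28 mm), a
cortical shell of constant normal width (default 359 μm) at fixed tissue
mineral density 1100 mgCaHA/cc, a uniform trabecular plateau (default
115 mg/cc, the 85–145 mg/cc apparent-BMD range), and cortical endplates
(0.8 mm) at both ends. The endosteal surface is the inward normal offset of
the periosteal ellipse, computed from an exact signed Euclidean distance
field, so the ground-truth width is well defined at every angle. Partial
volume at the analytic boundaries uses linear coverage ramps on a
supersampled grid (default 4× per axis; cohort simulations use 2×, at which
the 0.1 mm in-plane render step is already ~4× finer than the narrowest
PSF). Rendering refuses cortices thinner than one supersampled pixel.

An optional rod-lattice trabecular network (struts along all three axes)
is provided for BV/TV validation; its lattice-distance field is thresholded
to set *exactly* `round(BV/TV × n)` interior voxels to the strut density,
so the generator's achieved fill fraction is known without tolerance.

Longitudinal follow-ups add slabs of newly formed matrix flush to the
shell: density `f × 1100` (mineralization fraction `f`, default 0.5) over
the stated matrix width, inside the endosteal and/or outside the periosteal
boundary of the vertical wall. An optional TMD change applies to the
pre-existing shell. Blur plus block-average resampling conserves total
mineral mass to ~1e-9 relative on these phantoms — the identity the
deconvolution relies on.

Cohort generation draws per-subject cortical width, trabecular plateau and
apposition from arm-level normal distributions truncated at physiologic
bounds (width 150–800 μm, plateau 20–300 mg/cc, apposition ≥ 0). The
endosteal/periosteal split is drawn fully correlated (default 70% endosteal,
matching the observation that endosteal change dominates), so the total
apposition SD equals the sum of the per-surface SDs and reproduces the
printed total-change spread. Everything derives from one integer seed.

## Segmentation

The study-grade template-driven active-shape segmentation requires trained
anatomical templates and operator interaction; for convex, near-elliptic
phantoms an automated centroid-ray detector is sufficient and keeps the
pipeline deterministic. On each axial slice, radial profiles from the body
centroid locate the cortical ridge (profile maximum, required ≥ 200 mg/cc);
the periosteal and endosteal boundaries are placed where the profile falls
to half the ridge height **above the local baseline** on each side (outer:
soft tissue, inner: spongiosa plateau, each estimated ≥ 1.5 mm from the
ridge). An absolute 50%-of-ridge threshold would sit barely above a
100–145 mg/cc plateau and push the endosteal boundary arbitrarily deep;
half-maximum above baseline is the standard FWHM convention. Boundary radii
are median-filtered over angle (window 7, rejecting single-ray outliers),
Fourier low-passed (harmonics ≤ 8) and lightly smoothed axially. Slices
where fewer than 80% of rays detect the shell (the blurred body ends) are
dropped; segmentation fails if no usable slices remain or more than 20% of
retained rays are invalid.

For an **unresolved** shell the half-maximum boundary necessarily sits
~0.3–0.45 mm outside the true surface — this is the apparent-thickness
inflation (≈1.3 mm apparent vs ≈0.36 mm true) that the deconvolution
corrects, not a segmentation defect. Geometric boundary accuracy is
therefore validated on a resolvable 1.5 mm cortex (boundaries within one
voxel of the analytic surfaces, with or without noise); for the thin cortex
the segmentation's mid-surface is validated against the true shell
mid-line instead.

VOIs: the vertical cortex excludes an endplate fraction (default 15% of
body height) at each end; the subcortex is the 2 mm band inward of the
endosteal surface; the peeled spongiosa lies a further 2 mm deeper. Voxel
membership is decided by voxel-center location.

## Radial profiles and zones

All vertical-cortex-region voxels are pooled into nested 200 μm layers by
signed distance to the segmentation mid-surface (positive outward), from
−4 mm to +3 mm — topology is traded for noise suppression, since a single
subject contributes thousands of voxels per layer. Bins are half-open on
voxel-center distance; per-layer mean BMD forms the profile and mean BMD ×
layer thickness its BMC per unit wall area. Zone summaries re-center on the
ICON-fitted ridge and integrate the piecewise-constant profile with
partial-bin overlap weighting: periosteal +0.2…+0.6 mm, central ±0.2 mm,
endosteal −0.6…−0.2 mm, subcortical 2 mm band, spongiosa beyond.

## ICON deconvolution

The forward model is the closed-form Gaussian convolution of a piecewise-
constant profile: soft tissue `S` outside, spongiosa plateau `P` inside
(an edge spread function at the endosteal edge), and the cortical band at
fixed `T = 1100 mgCaHA/cc` between `c ± w/2` (a line spread function).
Baseline fitting is weighted nonlinear least squares over `(c, w, P, S, σ)`
with per-layer weights ∝ √(voxel count), σ initialized at the scanner
preset and bounded to ±50% of it (reconciling "scanner-specific" with
"estimated from the data"), `w` initialized from wCt.Th, and three
deterministic center starts (±1 layer) with best-residual selection. A
width collapsing to its lower bound is flagged degenerate rather than
reported. Because convolution preserves the band integral `w·(T − S)`,
the fitted width is robust to moderate σ misspecification (< 10% width
error for ±10% σ error).

Apposition fitting freezes the baseline geometry `(c, w, σ)` — the
follow-up is modeled as a refinement of the baseline — and fits two
nonnegative slabs flush to the band plus re-fitted `P` and `S`. The slabs
are parameterized internally by their mineral-equivalent width `h = f·a`
at full mineralization and the reported matrix width is `a = h/f`, so
estimates scale exactly as `1/f` (half the apposition under a
fully-mineralized assumption). The geometric difference between a slab of
density `f·T` and width `a` versus `T` and width `f·a` is second order in
`a/σ` (< 1% at study scale). Resorption is not represented by negative
widths; it is absorbed by the re-fitted plateau/soft-tissue levels.
One pooled profile is fitted per subject (per-sector fitting would trade
noise robustness for topology, against the design of the layering step).

## Thickness and cancellous metrics

Maximum-Sphere local thickness labels every cortical voxel with the
diameter of the largest sphere contained in the mask that covers the voxel
(the standard containing-sphere definition; the literal "sphere centered at
the voxel" variant is available via `sphere_radii`). Radii are physical
distances to the half-voxel surface between mask and background voxel
centers — so a 5-voxel slab at 0.2 mm spacing is labeled exactly 1.0 mm —
and coverage uses the closed-ball convention with a 1e-9 tie tolerance.
The implementation processes candidate radii in descending order with
EDT-based dilations; beyond 64 distinct radii they are floored onto a
uniform grid (a conservative quantization of at most half a voxel, only
reached on production-size masks). Ct.Th is the plain label mean over the
vertical cortex; wCt.Th weights each label by BMD/1100 as a first-order
partial-volume correction. BV/TV and TMD use a strict `> 250 mg/cc`
threshold ("above" read as strictly greater; boundary voxels excluded).

## Statistics

Per-subject changes (absolute and percent, percent computed per subject and
averaged, with the ratio-of-group-means also reported for cross-checking)
feed a one-way ANOVA across arms on change scores, pairwise equal-variance
Student's t-tests between arms (Welch optional), and paired t-tests within
arms against baseline, flagged at p < .05 without multiple-testing
correction.

## Validation strategy and limitations

Every estimator is tested against an independent oracle: closed-form
forward model vs brute-force numerical convolution; sphere labels vs
exhaustive center enumeration; binning vs per-voxel loops; calibration vs
normal equations; fits vs generate-and-fit round trips and grid scans. The
simulation reproduction images phantoms with a true 359 μm cortex under the
4:7:20 scanner mix and checks that apparent (~1.2–1.3 mm) and deconvolved
(~360 μm) thickness means emerge at study scale. Cohort-level ordering and
significance rates are evaluated on 100 generator draws at n = 11/12/8.

What passing these tests does *not* show: phantoms are convex, uniform and
perfectly registered between time points; real vertebrae have posterior
elements, heterogeneous trabecular structure, segmentation-template
variability and registration error, and real scanners have non-Gaussian
PSF tails and correlated noise. Cortical porosity is not measurable at this
resolution and is not modeled; the mineralization fraction of new matrix is
an assumption that linearly scales the reported apposition.
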