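# Methods

`osteolcn` re-implements, as a tested and reusable pipeline, the three
quantification workflows used to characterize the osteocyte
lacuno-canalicular network (LCN) in myeloma bone disease (MBD) mouse
models: 3D lacunar morphometry from synchrotron micro-CT of cortical
bone, 2D LCN quantification from Ploton silver-stained histology, and
relative gene expression (2^-ddCt) for a peri-lacunar remodeling (PLR)
gene panel. Because no raw scans or Ct tables are deposited for such
studies, every stage is validated by parameter recovery on synthetic data
whose generators encode the published group effect sizes.

## 3D lacunar morphometry

**Model of the data.** A cortical ROI is a slab of isotropic voxels
(default 0.65 um) containing bright mineralized bone and dark pores.
Osteocyte lacunae appear as enclosed ellipsoidal pores of roughly
25-2000 um^3; intracortical (vascular) canals are tubular pores well
above 2000 um^3; segmentation speckle is below 25 um^3.

**Pipeline.** (1) ROI slab selection: a slab of fixed physical extent
(default 0.5 mm) at a fixed offset (0.1 mm) distal of a reference slice.
The extent is floored to whole slices — 0.5 mm at 0.65 um/voxel is
exactly 769 slices — and the offset is rounded (154 slices). (2) Cortex
segmentation: a global threshold (Otsu's bimodal-histogram method in
`auto` mode; the skimage convention `intensity > threshold` is used
there, `>=` for explicit values) followed by a sweep that keeps only the
largest 26-connected component. (3) Optional trabecular removal, either
by an explicit mask or by dropping components not connected to the
cortical wall. (4) Pore extraction: the bone mask is hole-filled
(background connectivity 6, the complement of 26-connected foreground)
and subtracted from the filled mask; pores are labeled with
26-connectivity. The two slab cut faces are capped (treated as solid
during the fill) so pores bisected by the cut are retained; an
`exclude-cut` mode without capping is available. Because capping would
also enclose the medullary cavity, components that touch a cut face and
exceed an open-region cutoff (default 10^5 um^3, far above any canal in a
desk-scale slab and far below the cavity) are returned to background.
(5) Classification by volume bands: noise < 25 um^3 <= lacuna <
2000 um^3 <= canal, with boundary ties assigned to the higher band (the
published wording "less than"/"greater than" leaves equality undefined).
(6) Metrics over the lacuna class: density (count per mm^3 of filled
cortex = cortex + all enclosed pores), proportion (% of filled cortex),
mean volume, mean sphericity.

**Sphericity.** The Wadell index psi = pi^(1/3) (6V)^(2/3) / A with V
from the voxel count. A naive marching-cubes mesh of the binary pore
overestimates A by ~9% on curved surfaces (staircase facets), while
pre-smoothing the mask rounds sharp geometry and underestimates A there;
no single smoothing scale fixes both. The implementation therefore
meshes the Gaussian-smoothed mask at sigma = 1.0, 1.5 and 2.0 voxels and
extrapolates the three mesh areas quadratically to sigma = 0. On
digitized test solids this gives psi = 0.986 for a radius-20 sphere
(true 1.0), 0.806 for a side-20 cube (true 0.8060) and is within ~2% of
the closed form for prolate spheroids, including small lacuna-sized
ellipsoids. Pores thinner than 2 voxels in any axis get a missing value.
Smaller smoothing scales (0.5/0.75/1.0) and finally a raw mesh are used
as fallbacks for very small pores.

## 2D LCN quantification

**Binarization.** The silver stain is dark on light bone; pixels below
the threshold (Otsu inside the bone ROI by default) are stain. Lacuna
bodies are recovered by a morphological opening with a disk wider than
any canaliculus (default radius 3 px) and removed together with a 2 px
guard ring — the ring matters because the blurred boundary of a body
otherwise survives as a connected halo that fuses all canaliculi of that
lacuna into one component. Components longer than 60% of the field width
with near-unit eccentricity are flagged as cement lines and removed
(configurable; the original protocol removed them manually).

**Area fraction.** Network pixels as a percentage of bone area (ROI
minus removed body pixels), averaged over the fields of a sample.

**Canaliculus tracing.** The network is skeletonized. For each selected
lacuna (default: the 3 bodies nearest the field centroid that have at
least one emanating skeleton branch — the published protocol does not
say which 3 osteocytes were chosen; a seeded random alternative is a
flag) every skeleton branch crossing a ~3 px attachment shell around the
removed body region is followed outward to its first branch point (or,
behind a flag, through branch points along the most collinear
continuation, for the full visible projection). Length is the geodesic
step sum (1 px orthogonal, sqrt(2) px diagonal) times the pixel size,
plus the straight-line gap between the walk start and the detected body
boundary, so lengths are measured from the lacuna surface. Per-sample
mean over 3 lacunae per field x 3 fields (9 osteocytes), as in the
original protocol.

**Orientation.** Fields are acquired with lamellae horizontal, so
canaliculi run near-vertical. Each network component of at least 5 px
gets a major-axis angle from the image vertical via its second moments
(clockwise-positive, axial, wrapped to (-90, 90]). The residual lamellar
tilt — the area-weighted axial mean of the lacuna bodies' long-axis
angles from horizontal — is subtracted from every component angle; this
is mathematically the published "rotate the field until the lacunae are
horizontal" step applied to the measured angles instead of resampling
pixels. The statistic is the fraction of components within +/-20 degrees
of vertical; it is invariant to 180-degree field rotation.

## qPCR relative expression

dCt(sample, gene) = Ct_gene - Ct_reference (Gapdh);
ddCt = mean dCt(tumor) - mean dCt(control); fold change = 2^-ddCt using
group means, since the groups are independent animals (a per-sample
variant, the mean of 2^-(dCt - mean control dCt), is a flag). The group
test is an unpaired two-tailed Student's t-test on dCt (the log2 scale),
standard practice when the tested quantity is unstated. Amplification
efficiency correction and multi-reference normalization are out of
scope.

## Group statistics

All group comparisons use the classic pooled-variance two-tailed
Student's t-test (the default "unpaired t-test" of the cited analysis
software), reported as mean +/- SD with percent change
100 (tumor - naive)/naive and star annotations at .05/.01/.001/.0001
(half-open intervals). Zero-variance edge cases are defined explicitly:
identical constant groups give t = 0, p = 1; different constants give
p = 0. Welch's variant is available via `equal_var=False`. Type-I error
is verified by simulation (rejection rate 0.05 +/- 0.01 under the null).

## Synthetic data generators

The generators are first-class, tested code; their defaults are the
study conditions.

**3D volumes** emulate an annular cortical slab (outer radius 64 um,
wall 28 um, 144 x 208 x 208 voxels at 0.65 um) containing ellipsoidal
lacunae with random orientation (aspect ratios 2 : 1.2 : 1), two
full-length canals (radius 3 um) and 25 sub-resolution noise specks
(< 5 um^3), with Gaussian blur (0.5 um) and additive noise emulating the
imaging chain. Lacunar volumes are lognormal (shape 0.35) about a mean
of 200 um^3; the paper prints no absolute naive values, so the baseline
density (4 x 10^4 / mm^3) and mean volume are plausible murine
placeholders, and all acceptance checks use ratios between arms, never
absolute baselines. The lacuna count is deterministic,
round(density x wall volume), so that density recovery tests measure
segmentation and classification accuracy rather than Poisson sampling
noise; positions are random with non-overlap margins and bounded
retries. Ground truth (class, true analytic volume, rasterized voxel
count, centroid) is emitted per object, and the class volume bands are
guaranteed by construction. Not emulated: beam hardening, phase-contrast
fringes, anisotropic PSF, trabecular microarchitecture, osteocyte cell
bodies inside lacunae — so passing tests show correctness of the
morphometry operators on idealized geometry, not robustness to scanner
physics.

**2D fields** emulate a silver-stained field at 0.25 um/px (768 px =
192 um). Lacuna bodies (5 x 2.5 um semi-axes, major axis horizontal) sit
on a jittered grid whose spacing exceeds twice the canaliculus reach, so
fans of neighbouring lacunae cannot cross. Within a fan, angles about
the vertical are a stratified draw from the angular distribution
(wrapped normal, sd 15 degrees by default; uniform when the dispersion
is unset) — one draw per equal-probability stratum, which leaves the
marginal distribution unbiased while keeping neighbouring rays
angularly separated — and roots are spread left-to-right along the
body boundary in the same order as the sorted angles, which makes rays
of one fan provably non-crossing. Lengths are normal (15 +/- 2.5 um,
truncated at 3 sd). When a target LCN area fraction is set (default
0.06), detached short segments are added away from existing structures
until the network reaches it, so the area-fraction effect size is
encoded independently of the length effect. Real networks do cross and
branch; this generator deliberately trades that realism for exact
per-canaliculus ground truth.

**Ct tables** draw a per-sample loading offset (sd 0.5 cycles, cancels
in dCt by construction), a reference Ct of 18, per-gene baseline dCt of
5, the preset ddCt for tumor samples, and optional measurement noise on
every well. With zero noise the realized ddCt equals the preset exactly.
Group sizes default to 8 tumor vs 3 naive, as in the study design.

**Presets.** `u266_vs_nsg` (extensive disease): density x 0.80, mean
lacunar volume x 2.0, canaliculus length x 0.709, LCN area fraction
x 0.758, angular sd x 2 (the direction of the published orientation
change; its magnitude is unprinted, so a clearly detectable doubling is
used). `5tgm1_vs_bkal` (mild disease): length x 0.696 only. qPCR ddCt
offsets are -log2 of the printed fold changes (Dmp1 0.49, MMP13 4.9,
Ctsk 3.2, Acp5 7.7, MMP2 1.74, Sost 1.0).

## Problem sizes and numerical choices

Desk-scale defaults keep a full recovery study (10 seeded replicate
pairs of 3D volumes plus 10 pairs x 3 fields per arm for both models)
around two minutes: each 3D volume is ~6M voxels with ~33 naive
lacunae, each 2D field ~0.6M px with 9 lacunae x 10 canaliculi. Ratios
between arms are insensitive to these sizes; the residual quantization
of the deterministic lacuna count (round(0.8 x 33)/33 = 0.788 vs 0.80)
is well inside the +/-8-point acceptance band. All generators and
analyses are deterministic given their seeds; reruns are byte-identical
including CSV outputs.

## Known limitations

* Lacunae touching a canal merge into one 26-connected component and are
  classified as canal; the published processing is silent on this case
  and plain connectivity is followed (the synthetic generator keeps
  objects disjoint, so recovery tests do not exercise it).
* Sphericity of very small pores (minimum extent < ~6 voxels) is biased
  by a few percent despite the scale extrapolation; group comparisons of
  mean sphericity are still valid because both arms share the bias.
* The 2D canaliculus length is an apparent (projected, branch-limited)
  length, as in the original 2D protocol; no 3D network reconstruction
  is attempted.
* The cement-line heuristic (long + near-unit eccentricity) replaces a
  manual editing step and is configurable rather than validated against
  annotated data.
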