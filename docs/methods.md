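# Methods

`focusctu` implements a *focused-view* post-processing pipeline for CT
urography (CTU): starting from a multi-class segmentation of the urinary
tract on a contrast-enhanced CTU volume, it derives masks that keep only
the kidneys, ureters and bladder (plus a safety margin and bridged ureter
gaps) visible, registers the accompanying unenhanced CT into the CTU
frame, and replaces everything outside the mask with a fill value so that
anatomy outside the urinary tract — including incidental findings — is
concealed. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic test bed does and does not
show.

## Data model and conventions

Volumes are regular 3-D grids indexed `(x, y, z)` with `z` the
cranio-caudal axis, 0-based indices, and physical coordinates in
millimetres: voxel `(i, j, k)` sits at `origin + (i·sx, j·sy, k·sz)`.
Scalar volumes are Hounsfield units; label volumes use
`{0: background, 1: kidney, 2: ureter, 3: bladder}` and are stored as
unsigned 8-bit NIfTI. The reference working grid is 1 × 1 × 2 mm over a
192 × 160 × 256 mm field of view. Resampling preserves the physical
extent with the convention `dim_out = ceil(dim_in · sp_in / sp_out)` (the
field of view may grow by less than one voxel, never shrink); scalar
volumes interpolate linearly, labels nearest-neighbour.

## Focused-view masks

* **Method 1** — the segmentation itself: a voxel is visible iff its
  label is nonzero.
* **Method 2** — method 1 dilated by a sphere of physical radius
  `boundary_mm` (default 10 mm). Dilation is computed from the exact
  Euclidean distance transform with the grid spacing as sampling, so a
  voxel is included iff its *center* lies within the radius of a
  foreground voxel center; on anisotropic grids the structuring element
  is therefore ellipsoidal in index space. This definition is what the
  brute-force distance-scan oracle in the tests checks verbatim.
* **Method 3** — method 2 plus gap bridging. Connected components of the
  union of tract labels are computed under 26-connectivity (configurable).
  While more than one component remains, the algorithm selects a
  component containing ureter voxels (tie-break: smallest voxel count,
  then lowest lexicographic centroid), finds the closest voxel-center
  pair in millimetres between it and the nearest other component
  (surface-to-surface, not centroid-to-centroid: centroids of curved
  components can lie outside them), rasterizes the straight 3-D line
  between the pair, and merges the two components. Each added path is
  dilated by `bridge_radius_mm` (default 20 mm) *independently* of the
  method-2 boundary — the two dilations are unioned, never stacked — so
  `method1 ⊆ method2 ⊆ method3` holds by construction. Bridging may
  connect two ureter fragments to each other before reaching the kidney
  or bladder; the guarantee asserted at the end is that both kidneys and
  the bladder lie in one connected component. If the labels lack kidney
  or bladder voxels entirely, the remaining components are still
  connected best-effort and a warning is emitted.

Masking copies in-mask voxels exactly and writes `fill_hu`
(default −1024 HU, i.e. air — unambiguous "nothing here" in any CT
viewer) elsewhere; it is idempotent.

## Registration

The unenhanced volume is aligned to the CTU by maximizing the Pearson
cross-correlation of intensities under an affine transform (a rigid
restriction is available and is what the pipeline's recovery checks use,
since patient motion between the two acquisitions of one session is
rigid to good approximation). Optimization is regular-step gradient
descent seeded from the identity over a 3-level pyramid (shrink factors
4/2/1, smoothing 4/2/0 mm), with parameter scales derived from physical
shifts, full (non-random) metric sampling for determinism, 200
iterations per level, and a 1e-6 gradient tolerance; the machinery is
SimpleITK's registration framework, while the correlation metric
contract and the resampling conventions are implemented and tested in
this package. The exposed transform maps moving-frame physical points
into the fixed frame (`y = A x + t`); applying it resamples the moving
volume onto the fixed grid (linear for HU, nearest for masks,
out-of-field voxels filled). On phantoms, rigid recovery of misalignments
up to 10 mm / 10° is accurate to well under 1 mm and 1°; the
12-parameter affine is exposed as the general path but is less reliable
at the largest rotations because the correlation landscape lets scale
and rotation trade off.

## Synthetic phantom

The phantom emulates exactly the features the pipeline must handle, not
radiological realism: two ellipsoidal kidneys (semi-axes 22 × 18 × 38 mm),
tubular ureters (radius 4 mm) descending as smoothed polylines into an
ellipsoidal bladder (34 × 30 × 26 mm), inside an ellipsoidal soft-tissue
body with an air border. A voxel is labeled iff its center lies inside
the analytic shape (precedence on overlap: kidney > bladder > ureter, so
tube ends may dip into their anchor organs). Ureter centerlines are
arc-length resampled at 1 mm, which makes gap arithmetic exact: a gap
`(side, start fraction, length)` removes precisely the ureter voxels
whose nearest-centerline arc position falls in the interval — from the
*observed* labels only, never from the truth.

Intensities are fixture constants: soft tissue 40 HU, opacified
collecting system and bladder 300 HU, kidney parenchyma 140 HU
(nephrographic-phase enhancement; distinct from the excreted contrast so
the organ classes are not locally identical), unopacified tract 35 HU,
lesions 80 HU, air −1024 HU. Two phase-independent structures provide
the anatomy real registration relies on: perirenal fat capsules
(kidney ellipsoids scaled 1.35, −90 HU) and a vertebral-column surrogate
rod (radius 11 mm, 500 HU). Without them the unenhanced volume (whose
tract renders at 35 HU against 40 HU soft tissue) is nearly rotationally
featureless and rotation recovery is ill-posed. Noise is additive
i.i.d. Gaussian (default σ = 10 HU, typical of abdominal CT), drawn
independently for the two volumes from the spec's seed. The misalignment
is stored as the physical-space transform applied to the anatomy when
rendering the unenhanced volume, giving registration a parameter-recovery
ground truth.

Incidental lesions are validated to lie at least
`boundary + bridge radius + lesion radius` (default 10 + 20 + r mm) from
the tract, which makes concealment well-posed by construction: the
method-3 mask cannot reach them. What passing concealment tests show is
therefore that the mask machinery respects its stated radii — not that
real incidental findings always lie 30 mm from the urinary tract.

`default_spec` is deterministic; `random_spec(seed, ...)` jitters organ
centers (±5 mm), semi-axes (±10%), and interior ureter control points
(±4 mm), and injects gaps (default lengths 5–25 mm) and a random rigid
misalignment — the randomized study population for the property tests.
The `small` scale grids the common 192 × 160 × 256 mm anatomy at
2 × 2 × 4 mm (96 × 80 × 64 voxels); `standard` uses the working
1 × 1 × 2 mm grid.

What the phantom does *not* emulate: organ texture, beam hardening,
partial-volume blur, peristalsis-induced deformation (the misalignment is
globally rigid/affine), and anatomical variation beyond ellipsoid jitter.
Results on phantoms bound algorithmic correctness, not clinical
performance.

## Segmentation

The reference segmenter is a compact 3-D U-Net written in numpy with
hand-derived backpropagation (im2col convolutions; the gradient of each
layer is verified against float64 central differences in the tests).
Architecture: `depth` resolution levels, two 3×3×3 conv + instance norm +
ReLU blocks per level, 2×2×2 max pooling, nearest-neighbour upsampling
with skip concatenation, 1×1×1 softmax head. The training protocol is
cross-validation with the held-out fold as the validation portion,
categorical Dice loss with equal class weights
(`1 − mean_c (2Σpg + ε)/(Σp + Σg + ε)`, default ε = 1e-5), RMSProp
(ρ = 0.9), random crop sampling, best-validation-loss epoch retention per
fold, probability-averaging ensembling across folds, and sliding-window
inference (default stride: half patch, overlaps averaged in probability
space before the argmax). Intensities are clipped to [−1024, 600] HU and
scaled to [0, 1]. The full-scale defaults (192 × 160 × 128 patches at
1 × 1 × 2 mm, 5 folds, 250 epochs, learning rate 1e-4) describe the
protocol at clinical scale; they are not exercised on CPU.

The desk-scale configuration (`UNetConfig.small`: depth 2, 8 base
channels, 2 folds, 100 epochs, learning rate 3e-2 decayed ×0.3 at 70% of
training) makes one deliberate departure from stochastic-crop practice:
its patch (48 × 40 × 32 at a 4 × 4 × 8 mm working spacing) covers the
whole working volume, so each training step is a full-volume gradient on
a fixed finite sum. Two observations drove this. First, with only a few
hundred optimizer steps affordable on one CPU core, per-crop stochastic
Dice training reliably collapses into the all-background local optimum
(a suppressed empty class scores a perfect Dice under the ε convention,
and crops frequently miss the thin ureters entirely). Second, instance
norm makes features depend on per-window statistics, so predictions from
windows whose content mix differs from the training crops degrade;
full-volume patches make training and inference statistics identical.
When the working grid is coarser than the input volume, `predict` maps
the class probabilities back to the original grid by linear interpolation
and takes the argmax there, which preserves the 4 mm-radius ureters far
better than nearest-neighbour label upsampling. Under these conditions
the cross-validated ensemble reaches a mean foreground Dice of ≈ 0.89 on
four small phantoms (≈ 0.96 kidneys/bladder, ≈ 0.75 ureters) in about
nine minutes on one CPU core, and kidney/bladder Dice ≥ 0.6 transfers to
a held-out phantom. These thresholds and problem sizes are choices of
this package's test bed, not claims about clinical data.

## Reader-assessment statistics

Automated stand-ins for human ratings are coverage-based: per organ
instance, coverage is the fraction of ground-truth voxels inside the
mask. Kidneys and ureters are split left/right (by a phantom-provided
side map or by connected components ordered along x), and ureters are
optionally split into proximal/mid/distal by arc-length fractions
(default thirds) supplied by the phantom — a stand-in for the anatomical
landmarks (renal pelvis, external iliac artery crossing) a reader would
use, which phantoms cannot exhibit.

The printed 4-point visualization bins overlap at their boundaries; the
implementation fixes the exhaustive, disjoint reading
`(−, .75], (.75, .95], (.95, 1), {1}` with an optional tolerance on the
"complete" bin (default 0: coverage must be exactly 1). The 3-point
scale's "miniscule parts not visible" is a human judgment; the automated
default calls coverage ≥ 0.95 "miniscule" (configurable) — a stand-in,
flagged as such. Diagnostic ratios (sensitivity, specificity, PPV, NPV)
come from non-negative 2×2 counts and are `None` whenever their
denominator is zero — never silently 0. Cohen's κ uses marginal-based
chance agreement and is `None` when chance agreement is 1; it is
cross-checked against scikit-learn on random raters in the tests.
Percentages are reported to one decimal; the acceptance tests compare
summary proportions to within one unit of the last printed digit because
exact rounding of values like 37/39 and 26/39 is representation-dependent.

## Known limitations

* The phantom's HU palette and geometry are fixtures; no claim of
  intensity realism is made, and opacified/unopacified ureter statistics
  in particular are invented.
* Affine (as opposed to rigid) registration recovery degrades for
  rotations near 10°; the pipeline's guarantees are stated for the rigid
  model.
* The desk-scale segmenter is an architectural miniature; nothing about
  its clinical-scale behaviour is tested here.
* Bridging connects components by straight paths; strongly curved gaps
  longer than the bridge radius could in principle leave true ureter
  voxels outside the method-3 mask (phantom gaps up to 25 mm with the
  default 20 mm radius do not).
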