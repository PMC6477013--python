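# Methods

This note documents the models and procedures implemented in `kneeseg`,
the parameters that matter, the synthetic data used to validate them, and
the numerical conventions and known limitations.

## Image model and level set

The observed PDW volume is modeled as `V = b·J + n`: a piecewise-constant
tissue image `J` (one intensity per tissue), a smooth strictly positive
multiplicative bias field `b` (coil sensitivity / B1 inhomogeneity), and
zero-mean Gaussian noise `n`.  An edge-preserving mean-shift prefilter
(iterated range-weighted neighborhood means: flat spatial ball of radius 2
voxels, Gaussian range kernel at 10 % of the intensity range, 5 iterations)
suppresses `n`, so the working model is `V = b·J`.

The two-phase local-intensity-clustering energy is

    E(φ, c, b) = ∫ e₁(x) H_ε(φ(x)) + e₂(x) (1 − H_ε(φ(x))) dx
    e_i(x)     = ∫ K_σ(y − x) |V(x) − b(y) c_i|² dy

with `K_σ` a Gaussian kernel, `H_ε(x) = ½[1 + (2/π)arctan(x/ε)]` and its
derivative `δ_ε(x) = ε/(π(ε² + x²))`.  Minimization alternates three exact
coordinate updates per iteration — `c` (ratio of kernel sums), `b`
(pointwise ratio of two kernel convolutions), then an explicit gradient
step on φ with a length term `ν δ_ε(φ) div(∇φ/|∇φ|)` and a distance
regularization `μ(∇²φ − div(∇φ/|∇φ|))`.

Numerical conventions:

- `K_σ` is a separable Gaussian truncated at 4σ and normalized to unit sum;
  all convolutions use zero padding, so every kernel sum equals a
  brute-force direct summation exactly (tested to 1e-10).
- σ is given in voxels (default 4).  Spacing-aware kernels would matter for
  strongly anisotropic data; the intended inputs are resampled to 0.9 mm
  isotropic.
- Curvature uses central differences with |∇φ| floored at 1e-10; φ is
  clipped to ±10 after each step, which bounds the level-set function while
  keeping fronts mobile (δ_ε never vanishes).
- Intensities are rescaled (scale only, no shift — the multiplicative model
  is preserved) to 0..255 so that the default ν = 0.001·255² applies
  regardless of the input's units.
- Defaults: ν = 0.001·255², μ = 1, ε = 1, dt = 0.1, max 60 iterations,
  at least 5 (so c and b reach their joint fixed point even when the
  initialization is already accurate), stop when the zero set changes in
  fewer than 0.1 % of voxels.

Two choices deserve explanation:

- **Initialization.**  φ starts as ±2 on the top class of a 3-class
  multi-Otsu threshold.  A PDW knee histogram has at least three modes
  (background/ligament, muscle, marrow+fat); a single Otsu cut places
  muscle in the foreground, and because the clustering is local the bias
  field can absorb the muscle/marrow contrast, freezing a wrong but
  self-consistent labeling.  Local clustering has many such minima; a
  roughly correct initialization selects the right basin.
- **Membership sharpness ε_region.**  The arctan Heaviside has heavy tails:
  with ε = 1 and the bright phase occupying ~9 % of the field of view, the
  91 % outside voxels contribute ~15 % weight each to `c_inside`, pulling it
  from ~200 to ~135 and destabilizing the phase assignment.  The c/b update
  sums therefore use a sharper width ε_region = 0.05 (the evolution force
  keeps ε = 1).  The public update functions accept any ε, and the
  oracle tests exercise the generic form.

The bias field is defined up to a global scale (any factor can move between
`b` and the constants `c`); it is normalized to unit mean before the
correction `V_corrected = V / b` (with a floor of 1e-3).

**Limitation — bias validity near boundaries.**  `b̂` is a kernel-weighted
ratio; within ~σ of a phase boundary it mixes tissues whose intensity the
two-phase model represents with the wrong constant, producing a local dip.
Bias recovery is therefore evaluated on the trabecular interior eroded by
one kernel SD, where the estimate is clean (correlation with the phantom
truth ≥ 0.997 there, ~0.96 over the full compartment).  Likewise the
correction provably flattens the bright phase it models; tissues pooled
into the single outside constant (muscle, background) are not guaranteed to
improve.

## Rough bone isolation

The bright phase contains both bones' marrow plus infrapatellar fat.
Opening with a 5-mm spherical element (erosion, keep the two largest
26-connected components, dilation with the same element) removes thin
bridges and fat and splits the bones.  Erosion/dilation by a metric ball
are computed with the exact Euclidean distance transform — identical to the
explicit structuring element (tested), much faster for an 11-voxel-wide
ball, and with the desirable property that the volume boundary is not
treated as background (a shaft cut by the FOV edge is not eroded from that
side).  The component with the more superior centroid is the femur; a CLI
flag flips the axis convention.

## Normal rays and the intensity-line image

Per transverse slice, the rough mask boundary is extracted by marching
squares at level 0.5, resampled to 1-voxel arclength steps, and smoothed
with one circular [¼ ½ ¼] pass (removing the half-voxel staircase binary
masks induce).  At each contour point the tangent/normal frame comes from
the SVD of the mean-centered coordinates of the point and 4 neighbors per
side: the left singular vector of the larger singular value is the tangent,
the other the normal, oriented away from the contour centroid.  Normals are
computed in physical (mm) coordinates, so anisotropic in-plane spacing is
handled.

Sampling the bias-corrected volume by linear interpolation at
`base + t·normal`, t from −15 mm (inward) to +30 mm (outward) in steps of
the in-slice voxel size, gives one row per contour point: the IL2DI.
Out-of-bounds samples take the nearest in-bounds value and are flagged.
The (row, column) ↔ slice-coordinate map is retained and invertible.

## Trabecular boundary

Candidates on each row are the descents into local minima of the 3-sample
moving-average-smoothed profile: each candidate sits at the start of the
steepest negative first difference of its descent, with the descent's total
intensity loss as its strength.  At most 5 candidates are kept, and
descents below 10 % of the row's strongest are discarded — the
marrow-to-cortex edge is always high-contrast in PDW, while
bias-correction ripples otherwise produce percent-level descents that
compete on position alone.

Selection works on windows of M = 7 neighboring rows (circularly, shrunk
for very short contours).  Permutations pick one candidate per row;
any permutation with an adjacent-row jump above 5 samples is pruned (the
true boundary is smooth at 1-voxel ray spacing; enumeration is capped at
20 000 with a nearest-to-reference fallback).  Each permutation is scored

    f_STD · STDₙ / max STDₙ + f_DD · Σ|Pₙᵐ − P_ref| / max Σ|Pₙᵐ − P_ref|

with f_STD = f_DD = 1 and P_ref the rough boundary column; the center row
receives its candidate from the minimizing permutation (ties prefer the
candidate nearer the reference, then the smaller column).  On unpruned
instances the search equals exhaustive enumeration (tested).  Rows without
candidates are filled by circular linear interpolation.

Selected integer candidates are then localized to sub-sample precision at
the mid-amplitude crossing of their descent.  The integer sample marks the
last bright voxel; the physical edge lies within the following drop, and
mapping back integer samples biases the surface ~½–1 px inward.  Candidate
*selection* stays on integer samples.

The per-row positions are smoothed circularly (discrete Gaussian, kernel
size 3, σ = 1 row), then across slices (same kernel; rows of adjacent
slices matched by angular position around the contour centroid), mapped
back to slice coordinates, and rasterized to filled masks (self-
intersecting smoothed contours — checked with shapely — fall back to the
unsmoothed positions).

## Cortical boundary

The outer cortical edge mirrors the trabecular rule on ascents: candidates
are arrival samples of the steepest rises after local minima beyond the
trabecular boundary, at most 3, strongest first.  Cortical detection runs
on the raw (mean-shift denoised) profile: on a thin, near-one-sample
cortical trough with a bright inner (~200) and mid-gray outer (~100)
shoulder, the moving average displaces the minimum outward by 1–2 samples
and inflates thin-cortex thickness.

The iteration exploits two priors: cortical thickness varies smoothly and
thins toward the joint (inferior for the femur, superior for the tibia), and
weak edges are resolved from surrounding slices.  Slices are processed from
the thick shaft toward the thin joint end.  Per slice,

    R_MeanC = A_Cortical / C_TC,   C_TC = (outer + inner perimeter)/2

(per-slice profile smoothed by a 5-slice moving average) defines
P_Cmean = P_t + R_MeanC on every ray.  Candidates are re-selected with the
same windowed cost, referenced to P_Cmean; where the nearest incline
implies a thickness exceeding the matching rays (by contour angle) of the
last three processed slices *by more than one sample*, P_Cmean itself is
appended as a candidate; rays with no incline at all use P_Cmean directly.
The one-sample margin matters: the injected candidate has distance zero to
the reference and wins the cost whenever present, so injecting on
half-pixel quantization noise makes most of the bone track the prior and
the iteration drift; with the margin, only genuine weak-edge rays
(ligament) see the prior, and the iteration reaches a fixed point in 3–4
sweeps.

During the iteration R_MeanC is evaluated on the sub-sample contours
directly (shoelace area over polyline perimeters) — the same definition,
free of rasterization noise.  Convergence is declared when the summed
per-slice |ΔR_MeanC| drops below 1 pixel (threshold configurable); the
per-iteration change is written out as CSV.  Final positions are smoothed
and mapped back exactly like the trabecular contour, and the cortical mask
is the filled outer contour minus the trabecular mask.

**Limitation — oblique sections.**  Per-slice analysis measures apparent
in-plane thickness t/sin(tilt).  Where the bone surface tilts away from
the slice normal — the dome cap closing the joint end — the apparent
thickness necessarily rises; the thinning-trend checks therefore apply to
the quasi-cylindrical portion of the bone.

## Evaluation metrics

DSC = 2|A∩B|/(|A|+|B|) (1.0 for two empty masks, logged).  ASD is
symmetric: boundary voxels are mask voxels with a face-adjacent background
voxel; the mean distance from each boundary to the other (exact EDT in mm)
is averaged over both directions.  Both match all-pairs brute force on
small grids exactly.

## Synthetic phantoms

The generator emulates the tissue-contrast structure the pipeline assumes,
at the acquisition geometry of the intended inputs (0.9 mm isotropic,
default 96³):

- two bones side by side along the slice axis: femur superior, tibia
  inferior, overlapping spans in the middle ("joint"); elliptical
  cross-sections (shaft semi-axes 10×12 mm growing to 14×17 mm) with two
  condyle-like lobes emerging toward the joint end (mild concavity), shaft
  ends cut by the FOV, joint ends closed by a dome over 5 slices;
- a cortical shell of prescribed per-slice thickness, linear from 2.7 mm at
  the shaft to 0.6 mm at the joint, built by exact Euclidean-distance
  offset of the trabecular mask (floored at one voxel so the shell stays
  closed on the grid);
- class means background 15, trabecular 200, cortical 5, muscle 100,
  ligament 40, fat 230 (arbitrary units, PDW ordering);
- a dark ligament slab (3 mm) hugging the femoral cortex over a ±35°
  sector facing the tibia — the weak-edge failure mode;
- a bright 6-mm fat blob touching the femoral cortex at mid-shaft;
- bias `1 + A·G(x)`, G a unit-peak sum of three random smooth Gaussian
  bumps, A = 0.4 by default; additive Gaussian noise, SD 8 (≈ 4 % of the
  trabecular mean) — the paper-equivalent conditions are not quantified, so
  these are chosen as plausible for a modern 3-T acquisition;
- `volume = bias × class_mean[label] + noise`, exactly, voxelwise.

What the phantom does **not** emulate: partial-volume averaging at tissue
interfaces (class boundaries are voxel-sharp), Rician noise statistics,
texture within tissues, cartilage and menisci, and anatomical bone shape.
Consequences: sub-voxel boundary estimation cannot beat a voxel-exact rough
mask on this phantom (refinement monotonicity is therefore demonstrated
from deliberately displaced rough masks, which is also the regime the
refinement exists for), and passing scores here bound the method's
geometric and model-fitting behavior, not its robustness to scanner
physics.

## Problem sizes

The standard validation volume is 96³ at 0.9 mm (bones of 10–17 mm radius):
large enough for ~100-ray contours, 60-slice thickness profiles, and a
kernel width well below the bone radius, while a full pipeline run takes
~20 s.  Exact-oracle comparisons run on 8³ fields where brute-force direct
summation is affordable.
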