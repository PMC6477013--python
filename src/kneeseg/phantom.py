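"""Synthetic knee-like phantoms with known ground truth.

The phantom realizes the multiplicative image model V = b.J + noise that the
segmentation pipeline assumes: a piecewise-constant tissue image J (bright
trabecular compartment, nearly signal-free cortical shell, mid-intensity
muscle, dark ligament patches abutting the cortex, a bright fat blob touching
the bone), modulated by a smooth strictly positive bias field b, plus additive
Gaussian noise.

Geometry: two "bones" (femur superior, tibia inferior; axis 0 runs
superior->inferior) whose cross-sections are ellipses with slice-varying radii
that widen into two condyle-like lobes toward the joint end.  The cortical
shell has a prescribed thickness-per-slice profile that thins toward the
joint, built by an exact Euclidean-distance offset of the trabecular mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import VoxelGrid

TISSUE_LABELS = {
    "background": 0,
    "trabecular": 1,
    "cortical": 2,
    "muscle": 3,
    "ligament": 4,
    "fat": 5,
}

#: PDW-like contrast: fat and trabecular (fatty marrow) brightest, then
#: muscle, then ligament, and virtually no signal in cortical bone.
DEFAULT_CLASS_MEANS = {
    "background": 15.0,
    "trabecular": 200.0,
    "cortical": 5.0,
    "muscle": 100.0,
    "ligament": 40.0,
    "fat": 230.0,
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic knee phantom.

    The defaults define the standard test conditions used throughout the
    package: a 96^3 grid at 0.9 mm isotropic spacing, a 40% peak bias field,
    moderate Gaussian noise, a ligament slab on the femur (weak cortical
    edge) and cortical shells thinning from ~2.7 mm to ~0.6 mm toward the
    joint.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (0.9, 0.9, 0.9)
    class_means: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    #: (thick_mm_at_shaft, thick_mm_at_joint) for both bones
    cortical_thickness_mm: tuple[float, float] = (2.7, 0.6)
    #: explicit per-slice thickness profiles (mm); None -> linear from
    #: cortical_thickness_mm over each bone's slice span
    cortical_thickness_profile: dict | None = None
    bias_amplitude: float = 0.4
    noise_sd: float = 8.0
    rng_seed: int = 0
    #: shaft in-plane semi-axes (mm), (axis1, axis2)
    shaft_radii_mm: tuple[float, float] = (10.0, 12.0)
    #: joint-end in-plane semi-axes (mm)
    joint_radii_mm: tuple[float, float] = (14.0, 17.0)
    with_ligament: bool = True
    ligament_thickness_mm: float = 3.0
    with_fat_blob: bool = True
    fat_radius_mm: float = 6.0
    n_bones: int = 2

    def validate(self) -> None:
        if any(n < 32 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 32 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        means = self.class_means
        bright = min(means["trabecular"], means["fat"])
        others = [means[k] for k in ("muscle", "ligament", "background", "cortical")]
        if bright <= max(others):
            raise ValueError("class_means: trabecular and fat must be the brightest classes")
        if means["cortical"] >= min(means[k] for k in means if k != "cortical"):
            raise ValueError("class_means: cortical must be the darkest class")
        t0, t1 = self.cortical_thickness_mm
        if t1 > t0:
            raise ValueError(
                "cortical_thickness_mm must be non-increasing toward the joint "
                f"(got shaft {t0} < joint {t1})"
            )
        if t1 < 0:
            raise ValueError("cortical_thickness_mm must be non-negative")
        if t0 >= min(self.shaft_radii_mm):
            raise ValueError(
                f"cortical_thickness ({t0} mm) exceeds the bone radius "
                f"({min(self.shaft_radii_mm)} mm)"
            )
        if self.bias_amplitude <= -1:
            raise ValueError("bias_amplitude must exceed -1 to keep the bias field positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_bones not in (1, 2):
            raise ValueError("n_bones must be 1 or 2")


@dataclass
class PhantomTruth:
    """Ground truth bundle of a generated phantom."""

    volume: VoxelGrid
    trabecular_mask: np.ndarray  # both bones combined
    cortical_mask: np.ndarray
    bias_field: np.ndarray
    tissue_labels: np.ndarray
    bone_masks: dict  # {"femur": {"trabecular": ..., "cortical": ...}, ...}
    thickness_profile_mm: dict  # per-bone per-slice prescribed thickness (nan off-span)
    spec: PhantomSpec


def _bone_slice_spans(nz: int, n_bones: int) -> dict:
    """Slice span [start, stop) per bone; joint end is inferior for the femur
    and superior for the tibia.  Shaft ends run to the volume edge (the FOV
    cuts the shaft, as in a clinical knee scan); joint ends close inside the
    volume with a dome."""
    if n_bones == 1:
        return {"femur": (0, nz - 2)}
    return {
        "femur": (0, int(round(0.62 * nz))),
        "tibia": (int(round(0.38 * nz)), nz),
    }


#: slices over which the joint end tapers into a condyle dome
_N_DOME = 5


def _dome_scale(dist_from_joint_end: int) -> float:
    """In-plane radius scale for the rounded cap closing the joint end."""
    if dist_from_joint_end >= _N_DOME:
        return 1.0
    u = (_N_DOME - dist_from_joint_end) / (_N_DOME + 1)
    return float(np.sqrt(1.0 - u**2))


def _thickness_profiles(spec: PhantomSpec, spans: dict) -> dict:
    if spec.cortical_thickness_profile is not None:
        return {k: np.asarray(v, dtype=float) for k, v in spec.cortical_thickness_profile.items()}
    nz = spec.grid_shape[0]
    t_shaft, t_joint = spec.cortical_thickness_mm
    out = {}
    for bone, (z0, z1) in spans.items():
        prof = np.full(nz, np.nan)
        span = np.arange(z0, z1)
        frac = (span - z0) / max(z1 - 1 - z0, 1)
        if bone == "tibia":
            frac = 1.0 - frac  # joint (thin) end is superior for the tibia
        prof[span] = t_shaft + (t_joint - t_shaft) * frac
        out[bone] = prof
    return out


def _bone_trabecular_slice(shape2d, spacing2d, center, radii_mm, lobe_frac):
    """In-plane trabecular cross-section: main ellipse plus two condyle lobes.

    ``lobe_frac`` in [0, 1] scales lobe radius; 0 -> plain ellipse.
    """
    ii, jj = np.meshgrid(
        np.arange(shape2d[0]) * spacing2d[0],
        np.arange(shape2d[1]) * spacing2d[1],
        indexing="ij",
    )
    c1, c2 = center
    a, b = radii_mm
    mask = ((ii - c1) / a) ** 2 + ((jj - c2) / b) ** 2 <= 1.0
    if lobe_frac > 0:
        r_l = 0.55 * b * lobe_frac
        for sgn in (-1.0, 1.0):
            lc2 = c2 + sgn * 0.75 * b
            mask |= (ii - c1) ** 2 + (jj - lc2) ** 2 <= r_l**2
    return mask


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Generate a phantom volume with ground-truth masks and bias field.

    The returned volume satisfies, voxelwise and exactly,
    ``volume = bias_field * class_means[tissue_labels] + noise``.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    nz, ny, nx = spec.grid_shape
    sp = spec.spacing_mm
    rng = np.random.default_rng(spec.rng_seed)

    spans = _bone_slice_spans(nz, spec.n_bones)
    profiles = _thickness_profiles(spec, spans)

    # in-plane centers (mm); two bones side by side along axis 1
    fov1, fov2 = ny * sp[1], nx * sp[2]
    if spec.n_bones == 2:
        centers = {"femur": (0.33 * fov1, 0.5 * fov2), "tibia": (0.67 * fov1, 0.5 * fov2)}
    else:
        centers = {"femur": (0.5 * fov1, 0.5 * fov2)}

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    bone_masks = {b: {"trabecular": np.zeros(spec.grid_shape, bool),
                      "cortical": np.zeros(spec.grid_shape, bool)} for b in spans}

    for bone, (z0, z1) in spans.items():
        prof = profiles[bone]
        for z in range(z0, z1):
            frac = (z - z0) / max(z1 - 1 - z0, 1)
            if bone == "tibia":
                frac = 1.0 - frac  # widen toward the (superior) joint end
            a = spec.shaft_radii_mm[0] + (spec.joint_radii_mm[0] - spec.shaft_radii_mm[0]) * frac
            b = spec.shaft_radii_mm[1] + (spec.joint_radii_mm[1] - spec.shaft_radii_mm[1]) * frac
            d_joint = (z1 - 1 - z) if bone == "femur" else (z - z0)
            s = _dome_scale(d_joint)
            a, b = a * s, b * s
            lobe_frac = max(0.0, (frac - 0.6) / 0.4)
            trab = _bone_trabecular_slice((ny, nx), sp[1:], centers[bone], (a, b), lobe_frac)
            # exact uniform-thickness shell via Euclidean distance from the
            # trabecular surface; sub-voxel thicknesses are floored at one
            # voxel so the shell stays closed on the grid
            d_out = ndimage.distance_transform_edt(~trab, sampling=sp[1:])
            t_eff = max(prof[z], min(sp[1:])) if prof[z] > 0 else 0.0
            cort = (d_out > 0) & (d_out <= t_eff)
            bone_masks[bone]["trabecular"][z] = trab
            bone_masks[bone]["cortical"][z] = cort

    trab_all = np.zeros(spec.grid_shape, bool)
    for bone in spans:
        trab_all |= bone_masks[bone]["trabecular"]
    cort_all = np.zeros(spec.grid_shape, bool)
    for bone in spans:
        bone_masks[bone]["cortical"] &= ~trab_all
        cort_all |= bone_masks[bone]["cortical"]

    # leg envelope: everything inside is muscle unless claimed by another class
    ii, jj = np.meshgrid(np.arange(ny) * sp[1], np.arange(nx) * sp[2], indexing="ij")
    leg = ((ii - 0.5 * fov1) / (0.46 * fov1)) ** 2 + ((jj - 0.5 * fov2) / (0.46 * fov2)) ** 2 <= 1.0
    labels[:, leg] = TISSUE_LABELS["muscle"]

    # ligament: dark slab hugging the femoral cortex over a limited angular
    # sector (weak outer edge), mid-span slices
    if spec.with_ligament and "femur" in spans:
        z0, z1 = spans["femur"]
        lig_z = range(z0 + (z1 - z0) // 3, z1 - 2)
        c1, c2 = centers["femur"]
        ang = np.degrees(np.arctan2(jj - c2, ii - c1))  # 0 deg = +axis1 (toward tibia)
        sector = np.abs(ang) <= 35
        for z in lig_z:
            trab = bone_masks["femur"]["trabecular"][z]
            if not trab.any():
                continue
            d_out = ndimage.distance_transform_edt(~trab, sampling=sp[1:])
            t = profiles["femur"][z]
            lig = (d_out > t) & (d_out <= t + spec.ligament_thickness_mm) & sector & leg
            lig &= labels[z] == TISSUE_LABELS["muscle"]
            labels[z][lig] = TISSUE_LABELS["ligament"]

    # bright fat blob touching the femoral cortex (infrapatellar-fat analogue)
    if spec.with_fat_blob and "femur" in spans:
        z0, z1 = spans["femur"]
        frac = 0.45  # mid-shaft: the cortex there is thick enough to keep
        zc = (z0 + frac * (z1 - z0)) * sp[0]  # the fat 26-disconnected
        c1, c2 = centers["femur"]
        b_here = spec.shaft_radii_mm[1] + (spec.joint_radii_mm[1] - spec.shaft_radii_mm[1]) * frac
        t_here = spec.cortical_thickness_mm[0] + (
            spec.cortical_thickness_mm[1] - spec.cortical_thickness_mm[0]) * frac
        fc2 = c2 - (b_here + t_here + 0.85 * spec.fat_radius_mm)
        zz = np.arange(nz)[:, None, None] * sp[0]
        d2 = (zz - zc) ** 2 + (ii[None] - c1) ** 2 + (jj[None] - fc2) ** 2
        fat = d2 <= spec.fat_radius_mm**2
        fat &= labels != 0  # keep inside the leg
        labels[fat] = TISSUE_LABELS["fat"]

    labels[cort_all] = TISSUE_LABELS["cortical"]
    labels[trab_all] = TISSUE_LABELS["trabecular"]

    bias = _bias_field(spec, rng)
    means = np.array([spec.class_means[k] for k in
                      ("background", "trabecular", "cortical", "muscle", "ligament", "fat")])
    ideal = means[labels]
    volume = bias * ideal
    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, size=volume.shape)

    return PhantomTruth(
        volume=VoxelGrid(volume, spec.spacing_mm),
        trabecular_mask=trab_all,
        cortical_mask=cort_all,
        bias_field=bias,
        tissue_labels=labels,
        bone_masks=bone_masks,
        thickness_profile_mm=profiles,
        spec=spec,
    )


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + amplitude x (sum of Gaussian bumps,
    normalized to unit peak). Strictly positive for amplitude > -1."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    nz, ny, nx = spec.grid_shape
    zz, yy, xx = np.meshgrid(
        np.linspace(0, 1, nz), np.linspace(0, 1, ny), np.linspace(0, 1, nx), indexing="ij"
    )
    g = np.zeros(spec.grid_shape)
    n_bumps = 3
    centers = rng.uniform(0.15, 0.85, size=(n_bumps, 3))
    widths = rng.uniform(0.25, 0.45, size=n_bumps)
    weights = rng.uniform(0.5, 1.0, size=n_bumps)
    for (cz, cy, cx), w, a in zip(centers, widths, weights):
        g += a * np.exp(-((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2))
    g /= g.max()
    return 1.0 + spec.bias_amplitude * g


def generate_profile_fixture(
    bright: float = 100.0,
    trough: float = 5.0,
    rise_to: float = 60.0,
    bright_len: int = 12,
    descent_len: int = 1,
    trough_len: int = 4,
    rise_len: int = 1,
    tail_len: int = 12,
    rng_seed: int | None = None,
):
    """Build a 1D intensity profile shaped like a ray crossing a bone surface:
    bright plateau -> descent -> dark trough -> rise -> mid plateau.

    Returns ``(profile, annotations)`` where annotations carry the ground
    truth indices: ``P_t`` (last bright sample before the steepest drop),
    ``P_m`` (trough center) and ``P_c`` (first sample after the steepest
    rise).  With ``rng_seed`` set, plateau lengths are jittered
    reproducibly.
    """
    if rng_seed is not None:
        rng = np.random.default_rng(rng_seed)
        bright_len = int(bright_len + rng.integers(-2, 3))
        trough_len = int(trough_len + rng.integers(-1, 2))
        tail_len = int(tail_len + rng.integers(-2, 3))
    descent = np.linspace(bright, trough, descent_len + 2)[1:-1]
    rise = np.linspace(trough, rise_to, rise_len + 2)[1:-1]
    profile = np.concatenate([
        np.full(bright_len, bright),
        descent,
        np.full(trough_len, trough),
        rise,
        np.full(tail_len, rise_to),
    ])
    p_t = bright_len - 1
    trough_start = bright_len + descent_len
    p_m = trough_start + trough_len // 2
    p_c = trough_start + trough_len + rise_len
    if trough_len == 0:
        p_m = p_t + 1  # degenerate trough collapses onto the descent foot
    return profile, {"P_t": p_t, "P_m": p_m, "P_c": p_c}
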