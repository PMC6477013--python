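"""Precise trabecular boundary from the intensity-line image.

On every IL2DI row the bright marrow plateau drops toward the dark cortical
trough; candidate boundary points P_t are the steepest-descent samples
preceding local minima P_m (at most five, ranked by decline).  The boundary
is then chosen per row by scoring permutations of candidates over a window
of M neighboring rows:

    cost_n = f_STD * STD_n / max_n STD_n
           + f_DD  * sum_m |P_n^m - P_ref^m| / max_n sum_m |P_n^m - P_ref^m|

preferring candidate sequences that are mutually consistent (small standard
deviation) and close to a reference position (the rough level-set boundary
for the trabecular stage).  The winning positions are smoothed circularly in
the IL2DI view, smoothed across slices, and mapped back to filled slice
masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .raygeom import IntensityLineImage, PlanarContour, build_il2di, extract_slice_contours
from .types import VoxelGrid

log = logging.getLogger(__name__)

#: discrete Gaussian of kernel size 3 (sigma = 1 row), unit sum
_GAUSS3 = np.exp(-0.5 * np.array([1.0, 0.0, 1.0]))
_GAUSS3 /= _GAUSS3.sum()


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def smooth_row(row: np.ndarray) -> np.ndarray:
    """3-sample moving average with edge replication (suppresses single-sample
    noise minima before differencing)."""
    padded = np.concatenate([row[:1], row, row[-1:]])
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


@dataclass
class Candidate:
    p_t: int  # boundary candidate: start sample of the steepest drop
    p_m: int  # the local minimum the drop descends into
    decline: float  # intensity lost over the descent


@dataclass
class CandidateSet:
    row: int
    candidates: list = field(default_factory=list)

    @property
    def positions(self) -> list:
        return [c.p_t for c in self.candidates]

    def __len__(self) -> int:
        return len(self.candidates)


def _local_minima(s: np.ndarray) -> list[int]:
    """Interior local minima (first index of a plateau minimum)."""
    minima = []
    n = len(s)
    i = 1
    while i < n - 1:
        if s[i] < s[i - 1]:
            j = i
            while j + 1 < n and s[j + 1] == s[j]:
                j += 1
            if j < n - 1 and s[j + 1] > s[j]:
                minima.append(i)
            i = j + 1
        else:
            i += 1
    return minima


def detect_trabecular_candidates(
    row: np.ndarray,
    row_index: int = 0,
    max_candidates: int = 5,
    presmooth: bool = True,
    min_decline_fraction: float = 0.1,
) -> CandidateSet:
    """Candidate trabecular boundary points of one intensity line.

    For each local minimum of the (lightly smoothed) row, the candidate is
    the sample at the start of the steepest negative first difference in the
    descent preceding that minimum; the ``max_candidates`` of largest total
    decline are kept, ordered by decline.  A row without local minima yields
    an empty set (flagged for interpolation by the caller).

    Descents shallower than ``min_decline_fraction`` of the row's strongest
    decline are discarded: the marrow-to-cortex edge is always high-contrast
    in PDW, while bias-correction ripples produce percent-level descents
    that would otherwise compete on position alone.
    """
    if len(row) < 5:
        raise ValueError("row must have at least 5 samples")
    s = smooth_row(np.asarray(row, dtype=float)) if presmooth else np.asarray(row, dtype=float)
    d = np.diff(s)
    cands = []
    for p_m in _local_minima(s):
        start = p_m
        while start > 0 and d[start - 1] <= 0:
            start -= 1
        if start == p_m:
            continue
        drop_idx = start + int(np.argmin(d[start:p_m]))
        cands.append(Candidate(p_t=drop_idx, p_m=p_m, decline=float(s[start] - s[p_m])))
    if cands:
        floor = min_decline_fraction * max(c.decline for c in cands)
        cands = [c for c in cands if c.decline >= floor]
    cands.sort(key=lambda c: -c.decline)
    return CandidateSet(row=row_index, candidates=cands[:max_candidates])


# ---------------------------------------------------------------------------
# permutation cost (shared by the trabecular and cortical stages)
# ---------------------------------------------------------------------------

def enumerate_permutations(options: list[list[float]], max_jump: float | None, cap: int = 20000):
    """All sequences taking one option per row; with ``max_jump`` set, prune
    sequences whose adjacent-row difference exceeds it.  Returns None when
    the count would exceed ``cap``."""
    perms: list[list[float]] = [[]]
    for opts in options:
        nxt = []
        for p in perms:
            for o in opts:
                if max_jump is not None and p and abs(o - p[-1]) > max_jump:
                    continue
                nxt.append(p + [o])
            if len(nxt) > cap:
                return None
        perms = nxt
        if not perms:
            return []
    return perms


def score_permutations(
    perms: np.ndarray, refs: np.ndarray, f_std: float = 1.0, f_dd: float = 1.0
) -> np.ndarray:
    """The window cost: normalized standard deviation plus normalized summed
    distance to the per-row reference positions."""
    perms = np.asarray(perms, dtype=float)
    std = perms.std(axis=1)
    dd = np.abs(perms - refs[None, :]).sum(axis=1)
    max_std = std.max()
    max_dd = dd.max()
    cost = np.zeros(len(perms))
    if max_std > 0:
        cost += f_std * std / max_std
    if max_dd > 0:
        cost += f_dd * dd / max_dd
    return cost


def best_window_permutation(
    options: list[list[float]],
    refs: np.ndarray,
    center: int,
    f_std: float = 1.0,
    f_dd: float = 1.0,
    max_jump: float | None = 5.0,
    cap: int = 20000,
) -> float:
    """The winning candidate for the window's center row.

    Ties on cost prefer the permutation whose center candidate is nearer the
    center reference, then the smaller column.  Falls back to the per-row
    nearest-to-reference choice when pruning leaves no permutation or the
    enumeration would exceed ``cap``.
    """
    perms = enumerate_permutations(options, max_jump, cap)
    if not perms:  # None (over cap) or [] (pruned empty)
        return min(options[center], key=lambda o: (abs(o - refs[center]), o))
    perms = np.asarray(perms, dtype=float)
    cost = score_permutations(perms, np.asarray(refs, dtype=float), f_std, f_dd)
    best = np.min(cost)
    tied = np.flatnonzero(cost <= best + 1e-12)
    center_vals = perms[tied, center]
    order = np.lexsort((center_vals, np.abs(center_vals - refs[center])))
    return float(center_vals[order[0]])


# ---------------------------------------------------------------------------
# boundary selection over all rows
# ---------------------------------------------------------------------------

@dataclass
class BoundaryProfile:
    positions: np.ndarray  # per-row column (float)
    interpolated: np.ndarray  # True where the row had no candidates


def subsample_descent_edge(row: np.ndarray, p_t: int, p_m: int) -> float:
    """Sub-sample edge position of a bright-to-dark descent: where the
    profile crosses midway between the values at ``p_t`` and ``p_m``.

    The integer candidate marks the last bright sample; the physical
    boundary lies within the following drop.
    """
    hi, lo = row[p_t], row[p_m]
    mid = 0.5 * (hi + lo)
    for t in range(p_t, p_m):
        if row[t] >= mid >= row[t + 1] and row[t] > row[t + 1]:
            return t + (row[t] - mid) / (row[t] - row[t + 1])
    return p_t + 0.5


def subsample_ascent_edge(row: np.ndarray, p_m: int, p_c: int) -> float:
    """Sub-sample edge position of a dark-to-bright ascent ending at the
    arrival sample ``p_c``."""
    hi, lo = row[p_c], row[p_m]
    mid = 0.5 * (hi + lo)
    for t in range(p_m, p_c):
        if row[t] <= mid <= row[t + 1] and row[t + 1] > row[t]:
            return t + (mid - row[t]) / (row[t + 1] - row[t])
    return p_c - 0.5


def refine_positions_subsample(
    positions: np.ndarray, candidate_sets: list[CandidateSet], rows: np.ndarray,
    kind: str = "descent",
) -> np.ndarray:
    """Replace integer selected candidates by their sub-sample edge
    locations (rows interpolated from neighbors are left as-is)."""
    out = positions.astype(float).copy()
    for r, cs in enumerate(candidate_sets):
        for c in cs.candidates:
            if c.p_m >= 0 and abs(positions[r] - c.p_t) < 1e-9:
                s = np.asarray(rows[r], dtype=float)  # raw row: unbiased crossing
                if kind == "descent":
                    out[r] = subsample_descent_edge(s, int(c.p_t), c.p_m)
                else:
                    out[r] = subsample_ascent_edge(s, c.p_m, int(c.p_t))
                break
    return out


def _interpolate_empty(positions: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of missing rows."""
    n = len(positions)
    if not empty.any():
        return positions
    if empty.all():
        raise ValueError("every row has an empty candidate set")
    idx = np.flatnonzero(~empty)
    out = positions.copy()
    # unwrap circularly: interp on extended axis
    ext_idx = np.concatenate([idx - n, idx, idx + n])
    ext_val = np.tile(positions[idx], 3)
    out[empty] = np.interp(np.flatnonzero(empty), ext_idx, ext_val)
    return out


def select_boundary(
    candidate_sets: list[CandidateSet],
    refs: np.ndarray,
    m_window: int = 7,
    f_std: float = 1.0,
    f_dd: float = 1.0,
    max_jump: float | None = 5.0,
    cap: int = 20000,
) -> BoundaryProfile:
    """Choose one boundary position per IL2DI row by the windowed
    permutation cost, treating the rows as a closed (circular) sequence.

    ``refs`` is the per-row reference column (rough boundary P_TB for the
    trabecular stage; P_Cmean for the cortical one).  Rows with empty
    candidate sets are filled afterwards by circular linear interpolation.
    """
    if m_window % 2 != 1:
        raise ValueError("M must be odd")
    n = len(candidate_sets)
    refs = np.asarray(refs, dtype=float)
    empty = np.array([len(cs) == 0 for cs in candidate_sets])
    if empty.all():
        raise ValueError("every row has an empty candidate set")
    if empty.mean() > 0.2:
        log.warning("%.0f%% of rows have no boundary candidates", 100 * empty.mean())
    if n < m_window:  # short contour: shrink the window to the row count
        m_window = n if n % 2 == 1 else n - 1
    half = m_window // 2
    positions = np.full(n, np.nan)
    for r in range(n):
        if empty[r]:
            continue
        window = [(r + k) % n for k in range(-half, half + 1)]
        rows = [w for w in window if not empty[w]]
        options = [candidate_sets[w].positions for w in rows]
        center = rows.index(r)
        positions[r] = best_window_permutation(
            options, refs[rows], center, f_std, f_dd, max_jump, cap
        )
    return BoundaryProfile(
        positions=_interpolate_empty(positions, empty), interpolated=empty
    )


# ---------------------------------------------------------------------------
# smoothing and map-back
# ---------------------------------------------------------------------------

def smooth_circular(values: np.ndarray) -> np.ndarray:
    """Gaussian smoothing (kernel size 3, sigma 1) around a closed contour."""
    return (
        _GAUSS3[0] * np.roll(values, 1) + _GAUSS3[1] * values + _GAUSS3[2] * np.roll(values, -1)
    )


def _angles(il2di: IntensityLineImage) -> np.ndarray:
    pts = il2di.base_points
    c = pts.mean(axis=0)
    return np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])


def _interp_by_angle(ang_src: np.ndarray, val_src: np.ndarray, ang_query: np.ndarray) -> np.ndarray:
    """Circular interpolation of per-row values indexed by contour angle."""
    order = np.argsort(ang_src)
    a = ang_src[order]
    v = val_src[order]
    a_ext = np.concatenate([a - 2 * np.pi, a, a + 2 * np.pi])
    v_ext = np.tile(v, 3)
    return np.interp(ang_query, a_ext, v_ext)


def smooth_across_slices(
    displacements: dict[int, np.ndarray], il2dis: dict[int, IntensityLineImage]
) -> dict[int, np.ndarray]:
    """Smooth per-row boundary displacements in the slice direction.

    Rows of adjacent slices are matched by their angular position around the
    contour centroid; the same 3-tap Gaussian is applied (truncated and
    renormalized at the stack ends).
    """
    zs = sorted(displacements)
    angles = {z: _angles(il2dis[z]) for z in zs}
    out = {}
    for i, z in enumerate(zs):
        acc = _GAUSS3[1] * displacements[z]
        wsum = _GAUSS3[1]
        for k, w in ((-1, _GAUSS3[0]), (1, _GAUSS3[2])):
            j = i + k
            if 0 <= j < len(zs) and abs(zs[j] - z) == 1:
                zn = zs[j]
                acc = acc + w * _interp_by_angle(angles[zn], displacements[zn], angles[z])
                wsum += w
        out[z] = acc / wsum
    return out


def map_back(il2di: IntensityLineImage, positions: np.ndarray) -> np.ndarray:
    """IL2DI (row, position) cells to in-slice voxel coordinates."""
    sp = np.asarray(il2di.spacing_mm)
    base_mm = il2di.base_points * sp
    pos_mm = base_mm + (positions - il2di.origin_column)[:, None] * il2di.step_mm * il2di.normals
    return pos_mm / sp


def rasterize_contour(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled binary mask of a closed in-slice contour."""
    rr, cc = draw_polygon(points[:, 0], points[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return ndimage.binary_fill_holes(mask)


def _is_simple(points: np.ndarray) -> bool:
    try:
        return Polygon(points).is_valid
    except Exception:  # noqa: BLE001 - degenerate rings
        return False


# ---------------------------------------------------------------------------
# full trabecular refinement of one bone
# ---------------------------------------------------------------------------

@dataclass
class SliceBoundary:
    il2di: IntensityLineImage
    positions: np.ndarray  # smoothed per-row trabecular columns
    raw_positions: np.ndarray
    interpolated: np.ndarray


@dataclass
class TrabecularResult:
    mask: np.ndarray  # refined 3D trabecular mask
    slices: dict  # {z: SliceBoundary}


def refine_trabecular(
    vol_corrected: VoxelGrid,
    rough_mask: np.ndarray,
    n_neighbors: int = 4,
    inward_mm: float = 15.0,
    outward_mm: float = 30.0,
    step_mm: float | None = None,
    m_window: int = 7,
    f_std: float = 1.0,
    f_dd: float = 1.0,
    max_candidates: int = 5,
    max_jump: float | None = 5.0,
) -> TrabecularResult:
    """Refine the rough trabecular mask of one bone on the bias-corrected
    volume: IL2DI per slice, candidate detection, windowed selection against
    the rough boundary, circular + slice-direction smoothing, map-back."""
    slices: dict[int, SliceBoundary] = {}
    for z in range(rough_mask.shape[0]):
        if not rough_mask[z].any():
            continue
        contours = extract_slice_contours(rough_mask[z])
        if not contours:
            continue
        contour = PlanarContour(z, contours[0])
        il2di = build_il2di(vol_corrected, contour, n_neighbors, inward_mm, outward_mm, step_mm)
        cands = [
            detect_trabecular_candidates(il2di.rows[r], r, max_candidates)
            for r in range(il2di.n_rays)
        ]
        refs = np.full(il2di.n_rays, float(il2di.origin_column))
        profile = select_boundary(cands, refs, m_window, f_std, f_dd, max_jump)
        positions = refine_positions_subsample(profile.positions, cands, il2di.rows)
        slices[z] = SliceBoundary(
            il2di=il2di,
            positions=positions,
            raw_positions=positions.copy(),
            interpolated=profile.interpolated,
        )

    # circular smoothing, then slice-direction smoothing of displacements
    disp = {
        z: smooth_circular(sb.positions) - sb.il2di.origin_column for z, sb in slices.items()
    }
    disp = smooth_across_slices(disp, {z: sb.il2di for z, sb in slices.items()})

    mask = np.zeros_like(rough_mask, dtype=bool)
    shape2d = rough_mask.shape[1:]
    for z, sb in slices.items():
        positions = disp[z] + sb.il2di.origin_column
        pts = map_back(sb.il2di, positions)
        if not _is_simple(pts):
            log.warning("slice %d: smoothed contour self-intersects; using raw positions", z)
            positions = sb.raw_positions
            pts = map_back(sb.il2di, positions)
        sb.positions = positions
        mask[z] = rasterize_contour(pts, shape2d)
    return TrabecularResult(mask=mask, slices=slices)
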