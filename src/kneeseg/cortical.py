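"""Outer cortical boundary detection with an iterative thickness constraint.

The cortical shell is nearly signal-free, so along each IL2DI ray the outer
boundary is a rise from the dark trough back to soft-tissue intensity.  A
first guess takes the steepest incline after the first minimum beyond the
trabecular boundary; near ligaments (similarly dark, weak edge) this guess
can lock onto a ligament edge instead.  The fix exploits two anatomical
priors: the cortical thickness varies smoothly and thins toward the joint
(inferior for the femur, superior for the tibia), and experts resolve weak
edges from the surrounding slices.  Per slice, the mean thickness

    R_MeanC = A_Cortical / C_TC,   C_TC = (outer perimeter + inner perimeter) / 2

feeds a reference position P_Cmean = P_t + R_MeanC on every ray; candidates
(up to three strongest inclines, with P_Cmean injected whenever the nearest
incline implies a thickness larger than the matching rays of the last three
processed slices) are re-selected with the same windowed permutation cost as
the trabecular stage, iterating until the summed per-slice change of mean
thickness drops below one pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raygeom import IntensityLineImage
from .trabecular import (
    Candidate,
    CandidateSet,
    TrabecularResult,
    _angles,
    _interp_by_angle,
    _local_minima,
    map_back,
    rasterize_contour,
    refine_positions_subsample,
    select_boundary,
    smooth_across_slices,
    smooth_circular,
    smooth_row,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-row candidate detection
# ---------------------------------------------------------------------------

def detect_cortical_candidates(
    row: np.ndarray, p_t: int, max_candidates: int = 3, presmooth: bool = False
) -> CandidateSet:
    """Candidate outer-boundary points of one ray, searching beyond ``p_t``.

    Mirrors the trabecular rule on rising edges: for each local minimum after
    the trabecular boundary, the candidate is the arrival sample (first
    sample after) of the steepest positive first difference in the ascent
    that follows; the strongest ``max_candidates`` inclines are kept.

    Works on the raw (mean-shift denoised) row by default: on a thin, nearly
    one-sample cortical trough with a bright inner and mid-gray outer
    shoulder, a moving-average presmooth displaces the minimum outward.
    """
    s = smooth_row(np.asarray(row, dtype=float)) if presmooth else np.asarray(row, dtype=float)
    d = np.diff(s)
    n = len(s)
    cands = []
    minima = [m for m in _local_minima(s) if m > p_t]
    for p_m in minima:
        end = p_m
        while end < n - 1 and d[end] >= 0:
            end += 1
        if end == p_m:
            continue
        rise_idx = p_m + int(np.argmax(d[p_m:end]))
        cands.append(Candidate(p_t=rise_idx + 1, p_m=p_m, decline=float(s[end] - s[p_m])))
    cands.sort(key=lambda c: -c.decline)
    return CandidateSet(row=0, candidates=cands[:max_candidates])


def initial_cortical_guess(row: np.ndarray, p_t: int, presmooth: bool = False) -> int | None:
    """First cortical guess: steepest incline after the first local minimum
    beyond ``p_t`` (arrival-side sample), searching to the end of the ray.
    Returns None when there is no minimum or no rise (flagged row)."""
    s = smooth_row(np.asarray(row, dtype=float)) if presmooth else np.asarray(row, dtype=float)
    minima = [m for m in _local_minima(s) if m > p_t]
    if not minima:
        return None
    p_m = minima[0]
    d = np.diff(s)
    if p_m >= len(d) or np.max(d[p_m:]) <= 0:
        return None
    return p_m + int(np.argmax(d[p_m:])) + 1


# ---------------------------------------------------------------------------
# mean cortical thickness
# ---------------------------------------------------------------------------

def _perimeter_px(mask_slice: np.ndarray) -> float:
    from .raygeom import extract_slice_contours

    contours = extract_slice_contours(mask_slice)
    if not contours:
        return 0.0
    pts = contours[0]
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def mean_thickness(
    total_mask_slice: np.ndarray, trabecular_mask_slice: np.ndarray, pixel_mm: float = 1.0
) -> tuple[float, float]:
    """Slice mean cortical thickness R_MeanC = (A_total - A_trab) / C_TC.

    C_TC is the mean of the outer (total bone) and inner (trabecular)
    contour perimeters.  Returns (pixels, mm).
    """
    total = np.asarray(total_mask_slice, dtype=bool)
    trab = np.asarray(trabecular_mask_slice, dtype=bool)
    a_cort = float(total.sum() - trab.sum())
    p_out = _perimeter_px(total)
    p_in = _perimeter_px(trab)
    c_tc = 0.5 * (p_out + p_in)
    if c_tc <= 0:
        raise ValueError("zero perimeter: cannot compute mean cortical thickness")
    r_px = max(a_cort, 0.0) / c_tc
    return r_px, r_px * pixel_mm


def smooth_thickness_profile(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving average over ``window`` slices (edges truncated/renormalized)."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# iterative optimization
# ---------------------------------------------------------------------------

@dataclass
class CorticalState:
    """Per-slice cortical positions plus the thickness bookkeeping."""

    positions: dict  # {z: per-row cortical column}
    trab_positions: dict  # {z: per-row trabecular column} (fixed input)
    thickness_px: np.ndarray  # per processed slice, in processing order
    thickness_smoothed_px: np.ndarray
    converged: bool = False
    n_iter: int = 0
    change_history: list = field(default_factory=list)  # summed |dR| per iteration, px


@dataclass
class CorticalResult:
    cortical_mask: np.ndarray
    total_mask: np.ndarray
    state: CorticalState
    slices: dict  # {z: per-row smoothed cortical column}


def _slice_order(zs: list[int], bone: str) -> list[int]:
    """Processing order: thick shaft first, thinning toward the joint
    (superior->inferior for the femur, inferior->superior for the tibia,
    with axis 0 ordered superior->inferior)."""
    return sorted(zs) if bone == "femur" else sorted(zs, reverse=True)


def _thickness_cols(il2di: IntensityLineImage, r_px: float) -> float:
    """Convert a thickness in in-slice pixels to IL2DI columns."""
    pixel_mm = float(min(il2di.spacing_mm))
    return r_px * pixel_mm / il2di.step_mm


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _polyline_length(pts: np.ndarray) -> float:
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def _thickness_from_positions(
    order: list[int], slices: dict, positions: dict, trab_positions: dict
) -> np.ndarray:
    """Per-slice mean thickness (pixels) by the area-over-mean-perimeter rule
    evaluated on the sub-sample contours (A_cort / C_TC, continuous, so the
    iteration does not inherit rasterization noise)."""
    prof = np.empty(len(order))
    for i, z in enumerate(order):
        il2di = slices[z].il2di
        outer = map_back(il2di, positions[z])
        inner = map_back(il2di, trab_positions[z])
        a_cort = max(_polygon_area(outer) - _polygon_area(inner), 0.0)
        c_tc = 0.5 * (_polyline_length(outer) + _polyline_length(inner))
        prof[i] = a_cort / c_tc if c_tc > 0 else 0.0
    return prof


def _rebuild_masks(
    slices: dict, positions: dict, trab_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    total = np.zeros_like(trab_mask, dtype=bool)
    for z, sb in slices.items():
        pts = map_back(sb.il2di, positions[z])
        total[z] = rasterize_contour(pts, trab_mask.shape[1:]) | trab_mask[z]
    cortical = total & ~trab_mask
    return cortical, total


def refine_cortical(
    slices: dict,
    state: CorticalState,
    bone: str,
    m_window: int = 7,
    f_std: float = 1.0,
    f_dd: float = 1.0,
    max_candidates: int = 3,
    max_jump: float | None = 5.0,
    inject_margin: float = 1.0,
) -> CorticalState:
    """One re-selection sweep over all slices in the processing direction.

    Per row, the candidate set holds up to ``max_candidates`` strongest
    inclines; P_Cmean = P_t + R_MeanC is appended when the nearest incline
    implies a thickness exceeding the mean of the matching rays (by contour
    angle) over the last three processed slices.  Selection minimizes the
    windowed permutation cost with P_Cmean as the reference.
    """
    order = _slice_order(list(slices), bone)
    new_positions: dict[int, np.ndarray] = {}
    recent: list[tuple[np.ndarray, np.ndarray]] = []  # (angles, thickness_cols)
    for i, z in enumerate(order):
        sb = slices[z]
        il2di = sb.il2di
        n_rows = il2di.n_rays
        p_t = np.round(state.trab_positions[z]).astype(int)
        r_cols = _thickness_cols(il2di, state.thickness_smoothed_px[i])
        p_cmean = state.trab_positions[z] + r_cols
        angles = _angles(il2di)
        if recent:
            prior = np.mean(
                [_interp_by_angle(a, t, angles) for a, t in recent[-3:]], axis=0
            )
        else:
            prior = np.full(n_rows, r_cols)

        cand_sets = []
        for r in range(n_rows):
            cs = detect_cortical_candidates(il2di.rows[r], p_t[r], max_candidates)
            cands = [c for c in cs.candidates if c.p_t >= p_t[r]]
            if cands:
                first = min(c.p_t for c in cands)
                # inject the thickness-prior position only on a clear
                # violation: within one sample of the prior the nearest
                # incline is just the (quantized) cortical edge itself
                if first - state.trab_positions[z][r] > prior[r] + inject_margin:
                    cands.append(Candidate(p_t=float(p_cmean[r]), p_m=-1, decline=0.0))
            else:
                cands = [Candidate(p_t=float(p_cmean[r]), p_m=-1, decline=0.0)]
            cand_sets.append(CandidateSet(row=r, candidates=cands))

        n_empty_inclines = sum(1 for cs in cand_sets if cs.candidates[0].p_m == -1
                               and len(cs) == 1)
        if n_empty_inclines > 0.5 * n_rows:
            log.info("slice %d: %d/%d rows without inclines; using P_Cmean wholesale",
                     z, n_empty_inclines, n_rows)
            pos = p_cmean.copy()
        else:
            profile = select_boundary(cand_sets, p_cmean, m_window, f_std, f_dd, max_jump)
            pos = refine_positions_subsample(
                profile.positions, cand_sets, il2di.rows, kind="ascent"
            )
        pos = np.maximum(pos, state.trab_positions[z])  # cortex lies outward
        new_positions[z] = pos
        recent.append((angles, pos - state.trab_positions[z]))

    prof = _thickness_from_positions(order, slices, new_positions, state.trab_positions)
    state.positions = new_positions
    state.thickness_px = prof
    state.thickness_smoothed_px = smooth_thickness_profile(prof)
    return state


def detect_cortical(
    trab_result: TrabecularResult,
    trab_mask: np.ndarray,
    bone: str,
    m_window: int = 7,
    f_std: float = 1.0,
    f_dd: float = 1.0,
    max_candidates: int = 3,
    max_jump: float | None = 5.0,
    max_iter: int = 10,
    threshold_px: float = 1.0,
) -> CorticalResult:
    """Full cortical detection for one bone: initial steepest-incline guess,
    then iterative thickness-constrained re-selection until the summed
    per-slice mean-thickness change falls below ``threshold_px`` pixels."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    slices = trab_result.slices
    if not slices:
        raise ValueError("no slices to process")
    order = _slice_order(list(slices), bone)

    # Step 1: initial guess
    positions: dict[int, np.ndarray] = {}
    trab_positions = {z: sb.positions.copy() for z, sb in slices.items()}
    flagged: dict[int, np.ndarray] = {}
    for z in order:
        sb = slices[z]
        p_t = np.round(sb.positions).astype(int)
        pos = np.empty(sb.il2di.n_rays)
        flags = np.zeros(sb.il2di.n_rays, dtype=bool)
        for r in range(sb.il2di.n_rays):
            g = initial_cortical_guess(sb.il2di.rows[r], p_t[r])
            if g is None:
                flags[r] = True
                pos[r] = p_t[r]  # placeholder; replaced by P_Cmean next sweep
            else:
                pos[r] = max(g, sb.positions[r])
        if flags.all():
            raise ValueError(f"slice {z}: no cortical incline found on any row")
        if flags.any():
            ok = ~flags
            pos[flags] = np.interp(np.flatnonzero(flags), np.flatnonzero(ok), pos[ok])
        positions[z] = pos
        flagged[z] = flags

    prof = _thickness_from_positions(order, slices, positions, trab_positions)
    state = CorticalState(
        positions=positions,
        trab_positions=trab_positions,
        thickness_px=prof,
        thickness_smoothed_px=smooth_thickness_profile(prof),
    )

    # Step 2: iterate until the thickness profile stabilizes
    for it in range(1, max_iter + 1):
        prev = state.thickness_px.copy()
        refine_cortical(slices, state, bone, m_window, f_std, f_dd,
                        max_candidates, max_jump)
        change = float(np.abs(state.thickness_px - prev).sum())
        state.change_history.append(change)
        state.n_iter = it
        if change < threshold_px:
            state.converged = True
            break
    if not state.converged:
        log.warning("cortical optimization did not converge in %d iterations "
                    "(last change %.2f px)", max_iter, state.change_history[-1])

    # final smoothing (same as the trabecular stage) and map-back
    disp = {z: smooth_circular(state.positions[z]) - slices[z].il2di.origin_column
            for z in slices}
    disp = smooth_across_slices(disp, {z: sb.il2di for z, sb in slices.items()})
    final_positions = {
        z: np.maximum(disp[z] + slices[z].il2di.origin_column, trab_positions[z])
        for z in slices
    }
    cortical, total = _rebuild_masks(slices, final_positions, trab_mask)
    return CorticalResult(
        cortical_mask=cortical, total_mask=total, state=state, slices=final_positions
    )
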