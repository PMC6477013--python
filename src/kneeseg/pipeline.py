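"""End-to-end orchestration: prefilter -> 3DLICLS -> per-bone rough masks ->
bias correction -> IL2DI -> trabecular refinement -> iterative cortical
detection -> label map."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .cortical import CorticalResult, detect_cortical
from .licls import LiclsParams, correct_bias, mean_shift_filter, run_licls
from .metrics import evaluate
from .roughmask import isolate_bones
from .trabecular import TrabecularResult, refine_trabecular
from .types import EvalReport, VoxelGrid

log = logging.getLogger(__name__)

#: label map encoding
LABELS = {
    ("femur", "trabecular"): 1,
    ("femur", "cortical"): 2,
    ("tibia", "trabecular"): 3,
    ("tibia", "cortical"): 4,
}


@dataclass
class BoneResult:
    label: str
    rough_mask: np.ndarray
    trabecular: TrabecularResult
    cortical: CorticalResult


@dataclass
class PipelineResult:
    labelmap: np.ndarray
    bias: np.ndarray
    bones: dict  # {"femur": BoneResult, "tibia": BoneResult}
    licls_converged: bool
    timings_s: dict = field(default_factory=dict)

    def masks(self, bone: str, compartment: str) -> np.ndarray:
        return self.labelmap == LABELS[(bone, compartment)]


def run_pipeline(vol: VoxelGrid, config: PipelineConfig | None = None) -> PipelineResult:
    """Segment femur and tibia trabecular + cortical compartments.

    Returns a label map (1 femur-trabecular, 2 femur-cortical, 3
    tibia-trabecular, 4 tibia-cortical), the estimated bias field and all
    per-stage intermediates.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    filtered = mean_shift_filter(
        vol, cfg.ms_spatial_bandwidth, None if cfg.ms_range_fraction is None else
        cfg.ms_range_fraction * float(vol.data.max() - vol.data.min()),
        cfg.ms_iterations,
    )
    timings["mean_shift"] = time.perf_counter() - t0
    log.info("mean shift prefilter done (%.1f s)", timings["mean_shift"])

    t0 = time.perf_counter()
    licls = run_licls(filtered, LiclsParams(
        sigma=cfg.licls_sigma, nu=cfg.licls_nu, mu=cfg.licls_mu,
        epsilon=cfg.licls_epsilon, dt=cfg.licls_dt, max_iter=cfg.licls_max_iter,
        stop_fraction=cfg.licls_stop_fraction,
    ))
    timings["licls"] = time.perf_counter() - t0
    log.info("3DLICLS: %d iterations, converged=%s (%.1f s)",
             licls.n_iter, licls.converged, timings["licls"])

    t0 = time.perf_counter()
    femur, tibia = isolate_bones(
        licls.mask, vol.spacing_mm, cfg.radius_mm, cfg.superior_is_low_index
    )
    timings["roughmask"] = time.perf_counter() - t0

    corrected = correct_bias(filtered, licls.bias, cfg.bias_floor)

    bones: dict[str, BoneResult] = {}
    labelmap = np.zeros(vol.shape, dtype=np.uint8)
    for bone_mask in (femur, tibia):
        name = bone_mask.label
        t0 = time.perf_counter()
        trab = refine_trabecular(
            corrected, bone_mask.mask,
            n_neighbors=cfg.n_neighbors, inward_mm=cfg.inward_mm,
            outward_mm=cfg.outward_mm, step_mm=cfg.step_mm,
            m_window=cfg.m_window, f_std=cfg.f_std, f_dd=cfg.f_dd,
            max_candidates=cfg.trabecular_max_candidates, max_jump=cfg.max_jump,
        )
        timings[f"trabecular_{name}"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        cort = detect_cortical(
            trab, trab.mask, name,
            m_window=cfg.m_window, f_std=cfg.f_std, f_dd=cfg.f_dd,
            max_candidates=cfg.cortical_max_candidates, max_jump=cfg.max_jump,
            max_iter=cfg.cortical_max_iter, threshold_px=cfg.convergence_threshold_px,
        )
        timings[f"cortical_{name}"] = time.perf_counter() - t0
        log.info("%s: cortical converged=%s after %d iterations (changes: %s)",
                 name, cort.state.converged, cort.state.n_iter,
                 ", ".join(f"{c:.2f}" for c in cort.state.change_history))
        bones[name] = BoneResult(name, bone_mask.mask, trab, cort)
        labelmap[trab.mask] = LABELS[(name, "trabecular")]
        labelmap[cort.cortical_mask & (labelmap == 0)] = LABELS[(name, "cortical")]

    return PipelineResult(
        labelmap=labelmap, bias=licls.bias, bones=bones,
        licls_converged=licls.converged, timings_s=timings,
    )


def evaluate_against_truth(
    result: PipelineResult, truth_bone_masks: dict, spacing_mm
) -> dict[str, EvalReport]:
    """DSC/ASD per bone and compartment, plus combined bone masks, against
    phantom ground truth shaped like ``PhantomTruth.bone_masks``."""
    reports: dict[str, EvalReport] = {}
    for bone, compartments in truth_bone_masks.items():
        if bone not in result.bones:
            continue
        for comp, truth in compartments.items():
            pred = result.masks(bone, comp)
            if truth.any() and pred.any():
                reports[f"{bone}_{comp}"] = evaluate(pred, truth, spacing_mm)
        combined_truth = compartments["trabecular"] | compartments["cortical"]
        combined_pred = result.masks(bone, "trabecular") | result.masks(bone, "cortical")
        reports[f"{bone}_bone"] = evaluate(combined_pred, combined_truth, spacing_mm)
    return reports
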