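"""Pipeline configuration: every numeric constant used by any stage lives
here, readable from a TOML file with CLI overrides."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # mean shift prefilter
    ms_spatial_bandwidth: float = 2.0  # voxels
    ms_range_fraction: float = 0.1  # of the intensity range
    ms_iterations: int = 5
    # level set
    licls_sigma: float = 4.0  # voxels
    licls_nu: float = 0.001 * 255**2
    licls_mu: float = 1.0
    licls_epsilon: float = 1.0
    licls_dt: float = 0.1
    licls_max_iter: int = 60
    licls_stop_fraction: float = 0.001
    bias_floor: float = 1e-3
    # morphology
    radius_mm: float = 5.0
    superior_is_low_index: bool = True
    # intensity lines
    inward_mm: float = 15.0
    outward_mm: float = 30.0
    step_mm: float | None = None  # None -> in-slice voxel size
    n_neighbors: int = 4  # per side, for SVD normals
    # boundary selection
    m_window: int = 7
    f_std: float = 1.0
    f_dd: float = 1.0
    trabecular_max_candidates: int = 5
    cortical_max_candidates: int = 3
    max_jump: float = 5.0  # samples, adjacent-row pruning
    # cortical iteration
    convergence_threshold_px: float = 1.0
    cortical_max_iter: int = 10
    # misc
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # sections such as [licls] flatten by prefix
                for k, v in val.items():
                    flat[k if k in _FIELD_NAMES else f"{key}_{k}"] = v
            else:
                flat[key] = val
        unknown = set(flat) - _FIELD_NAMES
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_toml(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if v is None:
                    continue
                if isinstance(v, bool):
                    fh.write(f"{f.name} = {str(v).lower()}\n")
                elif isinstance(v, str):
                    fh.write(f'{f.name} = "{v}"\n')
                else:
                    fh.write(f"{f.name} = {v}\n")


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}
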