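"""Pipeline configuration and provenance records.

One YAML document drives every stage.  The schema is validated up front
(unknown keys are rejected) so a typo fails before any computation; every
output file gets a JSON provenance sidecar naming the stage, parameters,
input digests, seed and software version.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "PipelineConfig",
    "SimulationConfig",
    "TaskConfig",
    "load_config",
    "write_provenance",
    "file_digest",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


class TaskConfig(_StrictModel):
    """Block paradigm: alternating baseline/stimulus blocks."""

    n_blocks: int = 17
    duration_baseline_s: float = 18.0
    duration_stimulus_s: float = 12.0
    label_baseline: str = "opaque"
    label_stimulus: str = "transparent"
    n_runs_per_paradigm: int = 5
    beta_paradigm1: float = 2.0
    beta_paradigm2: float = 1.0
    n_volumes: int = 172


class NoiseChannelConfig(_StrictModel):
    n_per_coil: int = 5
    n_samples: int = 200000
    intra_corr: tuple[float, float] = (0.10, 0.11)
    intra_max: tuple[float, float] = (0.28, 0.29)
    inter_corr: float = 0.023
    inter_background: float = 0.01
    noise_level_ratio: float = 1.1019


class SimulationConfig(_StrictModel):
    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr_s: float = 1.5
    n_runs: int = 4
    n_volumes: int = 400
    baseline: float = 100.0
    sigma: float = 2.2
    ar1_phi: float = 0.3
    drift_coeffs: tuple[float, ...] = (0.0, 0.01, 0.005)
    rho: float = 0.3
    band_hz: tuple[float, float] = (0.01, 0.1)
    mask_box: Box = ((2, 14), (2, 14), (2, 10))
    roi_box: Box = ((5, 11), (5, 11), (4, 8))
    motion_translation_um: float = 140.0
    motion_rotation_deg: float = 0.6
    separation_cm: float = 11.0
    subject_ids: tuple[str, str] = ("sub-01", "sub-02")
    task: TaskConfig | None = Field(default_factory=TaskConfig)
    noise_channels: NoiseChannelConfig = Field(default_factory=NoiseChannelConfig)

    @field_validator("rho")
    @classmethod
    def _rho_range(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        return v


class PreprocessingConfig(_StrictModel):
    detrend_order: int = 5
    band_hz: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 1.5  # resting/synchrony pipeline; task pipeline uses 2.0
    fwhm_task_mm: float = 2.0


class SynchronyConfig(_StrictModel):
    threshold: float = 3.1
    two_sided: bool = False
    variance_stabilized: bool = True


class QcConfig(_StrictModel):
    tsnr_detrend_order: int = 2
    translation_bound_um: float = 140.0
    rotation_bound_deg: float = 0.6


class GlmConfig(_StrictModel):
    detrend_order: int = 5
    drift_high_hz: float = 0.01
    paired_threshold_t: float = 2.26
    unpaired_threshold_z: float = 1.96


class PipelineConfig(_StrictModel):
    seed: int = 0
    out_dir: str = "hyperbold_out"
    orientation: tuple[str, str, str] = ("L", "A", "S")
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    synchrony: SynchronyConfig = Field(default_factory=SynchronyConfig)
    qc: QcConfig = Field(default_factory=QcConfig)
    glm: GlmConfig = Field(default_factory=GlmConfig)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML config; omitted path gives the defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return PipelineConfig.model_validate(data)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    output_path: str | Path,
    stage: str,
    parameters: dict,
    seed: int,
    inputs: list[str | Path] | None = None,
) -> Path:
    """Write ``<output>.prov.json`` describing how the output was produced."""
    from . import __version__

    record = {
        "stage": stage,
        "parameters": parameters,
        "seed": seed,
        "inputs": {str(p): file_digest(p) for p in (inputs or [])},
        "software": {"package": "hyperbold", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov_path = Path(str(output_path) + ".prov.json")
    prov_path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return prov_path
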