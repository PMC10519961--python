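"""Pipeline configuration: YAML-backed, schema-validated, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Strict):
    width: int = 128
    height: int = 128
    pixel_spacing: float = 250.0
    n_nuclei: int = 12
    nucleus_radius_mean: float = 3.0
    nucleus_radius_sd: float = 0.5
    noise_sd: float = 0.02


class ScanBlock(_Strict):
    enabled: bool = False
    fast_freq: float = 20.0
    prr: float = 20000.0
    sample_rate: float = 200000.0
    duration: float = 1.0
    window: int = 5
    method: str = "linear"        # gridding method; 'sibson' is exact but slower
    grid_spacing_um: float | None = None


class TrainBlock(_Strict):
    iterations: int = 60
    base_width: int = 8
    n_res_blocks: int = 2
    disc_width: int = 8
    lambda_cyc: float = 150.0
    lr: float = 2e-4
    patch: int = 64


class RegistrationBlock(_Strict):
    affine_iters: int = 300
    demons_iters: int = 30
    demons_levels: int = 3
    demons_smoothing: float = 2.0


class SimilarityBlock(_Strict):
    lpf: bool = True
    lpf_target_resolution: float = 2.0


class NucleiBlock(_Strict):
    stain_method: str = "macenko"
    min_diameter: float = 6.0
    max_diameter: float = 50.0


class ReaderBlock(_Strict):
    n_items: int = 24
    n_raters: int = 5
    n_positive: int = 10
    error_rate: float = 0.1


class PipelineConfig(_Strict):
    """Top-level configuration; every stage draws randomness from ``seed``."""

    seed: int = 0
    out_dir: str = "virthist_out"
    stages: list[str] = [
        "phantom", "encode", "train", "infer", "register",
        "similarity", "nuclei", "readerstats",
    ]
    logging_level: str = "INFO"
    phantom: PhantomBlock = PhantomBlock()
    scan: ScanBlock = ScanBlock()
    train: TrainBlock = TrainBlock()
    registration: RegistrationBlock = RegistrationBlock()
    similarity: SimilarityBlock = SimilarityBlock()
    nuclei: NucleiBlock = NucleiBlock()
    readerstats: ReaderBlock = ReaderBlock()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)
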