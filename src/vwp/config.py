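"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class PreprocessConfig:
    kernel_size: int = 8
    background_sigma: float = 50.0
    channel: str = "green"


@dataclass
class GradientConfig:
    neighborhood: int = 9
    thr_scope: float = 0.5
    deviation_form: bool = False


@dataclass
class SGLDConfig:
    d_range: tuple[int, int] = (2, 30)
    candidate_widths: tuple[int, ...] = (16, 32, 64)
    delta: int = 16


@dataclass
class WallConfig:
    width_range: tuple[float, float] = (5.0, 50.0)
    percentile_thr: float = 0.90
    block: int = 32
    rim_margin: int = 10
    local_dominance: float = 0.85
    dominance_window: int = 17
    cos_tol: float = float(np.cos(np.deg2rad(160.0)))
    angle_tol: float = float(np.deg2rad(20.0))
    inclusion_radius: int = 12
    min_size: int = 10
    max_steps: int = 10
    prune_mode: str = "region_growing"
    dark_vessels: bool = False


@dataclass
class MFConfig:
    n_angles: int = 12
    n_scales: int = 4
    elongation: float = 2.0
    mode: str = "single_mode"
    sided: str = "double_sided"
    as_printed: bool = False


@dataclass
class DetectConfig:
    th_mfr: float = 0.5
    r_l: int = 12
    max_bad_fraction: float = 0.25
    site_mode: str = "centerline"
    gap_max: int = 5
    grow_steps: int = 8


@dataclass
class EvalConfig:
    r_l_grid: tuple[int, ...] = (6, 12, 25)
    th_mfr_grid: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    tolerant: bool = False


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    sgld: SGLDConfig = field(default_factory=SGLDConfig)
    wall: WallConfig = field(default_factory=WallConfig)
    mf: MFConfig = field(default_factory=MFConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "preprocess", "gradient", "sgld", "wall", "mf", "detect", "eval",
            ):
                sub = {
                    "preprocess": PreprocessConfig,
                    "gradient": GradientConfig,
                    "sgld": SGLDConfig,
                    "wall": WallConfig,
                    "mf": MFConfig,
                    "detect": DetectConfig,
                    "eval": EvalConfig,
                }[f.name]
                sub_kwargs = {}
                for sf in dataclasses.fields(sub):
                    if sf.name in v:
                        val = v[sf.name]
                        if isinstance(val, list):
                            val = tuple(val)
                        sub_kwargs[sf.name] = val
                kwargs[f.name] = sub(**sub_kwargs)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})
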