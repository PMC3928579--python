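"""Pipeline configuration.

All tunable constants of the analysis live here with their defaults:
the 3x3x3 median mask, the disk threshold fraction p_m = 2/3, the
gradient floor used when tracing the RNFL lower boundary, the active-edge
correction window, the 150 um cup offset, the 360 one-degree polar bins
and the linear BGA-to-MD conversion (slope 24 dB per unit, intercept
-9.34 dB). Keeping them in one dataclass means no stage hard-codes a
constant and a config file can override any of them.
"""

from __future__ import annotations

import configparser
import dataclasses
from pathlib import Path

from .errors import ConfigError


@dataclasses.dataclass
class PipelineConfig:
    # pre-processing
    median_mask: tuple[int, int, int] = (3, 3, 3)
    border: str = "replicate"  # or "reflect"
    # segmentation
    p_m: float = 2.0 / 3.0
    disk_threshold_mode: str = "reciprocal"  # or "literal"
    otsu_scope: str = "bscan"  # or "volume"
    gradient_floor: float = 2.0  # gray levels; 0 = literal first-positive-edge rule
    refine_window: tuple[int, int] = (5, 5)  # rows above / below the candidate edge
    # geometry
    cup_offset_um: float = 150.0
    polar_bins: int = 360
    eye: str = "right"  # or "left"; mirrors the TSNIT quadrant labels
    # MD conversion model
    md_slope: float = 24.0
    md_intercept: float = -9.34
    # randomness (phantom generation, cohort simulation)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.median_mask) != 3 or any(d < 1 for d in self.median_mask):
            raise ConfigError(f"median_mask must be three positive ints, got {self.median_mask}")
        if self.border not in ("replicate", "reflect"):
            raise ConfigError(f"border must be 'replicate' or 'reflect', got {self.border!r}")
        if not 0 < self.p_m < 1:
            raise ConfigError(f"p_m must lie in (0, 1), got {self.p_m}")
        if self.disk_threshold_mode not in ("reciprocal", "literal"):
            raise ConfigError(f"unknown disk_threshold_mode {self.disk_threshold_mode!r}")
        if self.otsu_scope not in ("bscan", "volume"):
            raise ConfigError(f"unknown otsu_scope {self.otsu_scope!r}")
        if self.gradient_floor < 0:
            raise ConfigError("gradient_floor must be >= 0")
        if self.cup_offset_um <= 0:
            raise ConfigError("cup_offset_um must be positive")
        if self.polar_bins < 4:
            raise ConfigError("polar_bins must be >= 4")
        if self.eye not in ("right", "left"):
            raise ConfigError(f"eye must be 'right' or 'left', got {self.eye!r}")

    # ------------------------------------------------------------------ io
    _SECTIONS = {
        "preprocess": ("median_mask", "border"),
        "segmentation": (
            "p_m",
            "disk_threshold_mode",
            "otsu_scope",
            "gradient_floor",
            "refine_window",
        ),
        "geometry": ("cup_offset_um", "polar_bins", "eye"),
        "md_model": ("md_slope", "md_intercept"),
        "random": ("seed",),
    }

    def to_ini(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {}
            for key in keys:
                value = getattr(self, key)
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                cp[section][key] = str(value)
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        cp = configparser.ConfigParser()
        cp.read(path)
        kwargs: dict = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for section in cp.sections():
            for key, raw in cp[section].items():
                if key not in fields:
                    continue
                kind = fields[key].type
                if key in ("median_mask", "refine_window"):
                    kwargs[key] = tuple(int(v) for v in raw.split(","))
                elif kind == "int" or key == "seed" or key == "polar_bins":
                    kwargs[key] = int(raw)
                elif kind == "float" or key in ("p_m", "gradient_floor", "cup_offset_um",
                                                "md_slope", "md_intercept"):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)
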