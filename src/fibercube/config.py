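"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from fibercube.geometry import BundleLayout
from fibercube.simulate import DetectorConfig, SpectralLibrary, default_library

__all__ = ["PipelineConfig", "DEFAULT_PEAKS"]

# substance -> characteristic shift (cm^-1) and fit-window width
DEFAULT_PEAKS: dict[str, dict[str, float]] = {
    "PS": {"shift": 1035.0, "window": 40.0},
    "PMMA": {"shift": 600.0, "window": 40.0},
    "paracetamol": {"shift": 860.0, "window": 40.0},
    "aspirin": {"shift": 1047.0, "window": 40.0},
    "caffeine": {"shift": 1703.0, "window": 40.0},
    "teflon": {"shift": 734.0, "window": 40.0},
}


@dataclass
class PipelineConfig:
    layout: BundleLayout = field(default_factory=BundleLayout)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    library: SpectralLibrary = field(default_factory=default_library)
    seed: int = 0
    # spectral axis: (lo, hi, step) in cm^-1
    axis: tuple[float, float, float] = (200.0, 2000.0, 2.0)
    baseline_order: int = 4
    baseline_iterations: int = 15
    wavelength_degree: int = 3
    peaks: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PEAKS.items()})
    normalization_window: tuple[float, float] | None = None
    # simulation options
    phantom: str = "fig9"            # fig9 | half_field | three_phase | uniform:<name>
    illumination_ratio: float = 10.0
    science_amplitude: float = 8000.0
    fluorescence_scale: float = 800.0
    optics_background: float = 500.0
    reference_amplitude: float = 6000.0
    n_bias: int = 3
    n_arc_lines: int = 8
    n_cosmics: int = 20
    throughput_spread: float = 0.08
    # optional paths to pre-recorded frames (skips simulation)
    frames: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi, step = self.axis
        if not (lo < hi and step > 0):
            raise ValueError("axis must satisfy lo < hi with positive step")
        for name, spec in self.peaks.items():
            if not lo <= spec["shift"] <= hi:
                raise ValueError(f"peak {name!r} at {spec['shift']} cm^-1 "
                                 f"falls outside the axis [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "layout" in raw:
            kwargs["layout"] = BundleLayout.from_dict(raw["layout"])
        if "detector" in raw:
            kwargs["detector"] = DetectorConfig(**raw["detector"])
        if "library" in raw:
            kwargs["library"] = SpectralLibrary.from_dict(raw["library"])
        if "axis" in raw:
            kwargs["axis"] = tuple(float(v) for v in raw["axis"])
        if "normalization_window" in raw and raw["normalization_window"]:
            kwargs["normalization_window"] = tuple(raw["normalization_window"])
        for key in ("seed", "baseline_order", "baseline_iterations",
                    "wavelength_degree", "peaks", "phantom",
                    "illumination_ratio", "science_amplitude",
                    "fluorescence_scale", "optics_background",
                    "reference_amplitude", "n_bias", "n_arc_lines",
                    "n_cosmics", "throughput_spread", "frames"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "layout": {
                "n_rows": self.layout.n_rows, "n_cols": self.layout.n_cols,
                "pitch_mm": self.layout.pitch_mm,
                "core_um": self.layout.core_um,
                "cladding_um": self.layout.cladding_um,
                "dead_fibers": sorted(list(rc) for rc in self.layout.dead_fibers),
            },
            "detector": {
                "n_rows_px": self.detector.n_rows_px,
                "n_cols_px": self.detector.n_cols_px,
                "bias_level": self.detector.bias_level,
                "read_noise": self.detector.read_noise,
                "gain": self.detector.gain,
            },
            "seed": self.seed,
            "axis": list(self.axis),
            "baseline_order": self.baseline_order,
            "baseline_iterations": self.baseline_iterations,
            "wavelength_degree": self.wavelength_degree,
            "peaks": self.peaks,
            "normalization_window": list(self.normalization_window)
            if self.normalization_window else None,
            "phantom": self.phantom,
            "illumination_ratio": self.illumination_ratio,
            "science_amplitude": self.science_amplitude,
            "fluorescence_scale": self.fluorescence_scale,
            "optics_background": self.optics_background,
            "reference_amplitude": self.reference_amplitude,
            "n_bias": self.n_bias,
            "n_arc_lines": self.n_arc_lines,
            "n_cosmics": self.n_cosmics,
            "throughput_spread": self.throughput_spread,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
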