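"""Layered pipeline configuration (YAML file + CLI overrides)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .contractility import DetectionConfig, TraceConfig
from .errors import InvalidConfigError
from .transform import PolarTransformConfig


@dataclass
class PipelineConfig:
    """Everything the ``assess`` pipeline needs, in one flat record.

    ``roi`` is ``(top, left, height, width)``; ``None`` analyzes the full
    frame (which must then already be an even square).  Exactly one of
    ``mask`` or ``make_mask`` must be given; a supplied mask file always
    wins over the threshold helper.
    """

    input: str | None = None
    mask: str | None = None
    make_mask: str | None = None  # None | "otsu" | "fixed"
    threshold_level: float | None = None
    fps: float | None = None
    roi: tuple[int, int, int, int] | None = None
    radial_oversample: int = 2
    angular_oversample: int = 2
    kernel: str = "trig"
    reference: str = "first"
    threshold_mads: float = 5.0
    baseline_window_s: float = 2.0
    min_separation_s: float | None = None
    stim_freq_hz: float | None = None
    out_dir: str = "cardiotrace_out"
    seed: int = 0
    log_level: str = "INFO"
    plot: bool = False

    def __post_init__(self) -> None:
        if self.make_mask not in (None, "otsu", "fixed"):
            raise InvalidConfigError(f"make_mask must be otsu or fixed, got {self.make_mask!r}")
        if self.kernel not in ("trig", "cubic"):
            raise InvalidConfigError(f"kernel must be trig or cubic, got {self.kernel!r}")
        if self.reference not in ("first", "rest"):
            raise InvalidConfigError(f"reference must be first or rest, got {self.reference!r}")
        if self.radial_oversample < 1 or self.angular_oversample < 1:
            raise InvalidConfigError("oversampling factors must be >= 1")
        if self.threshold_mads <= 0 or self.baseline_window_s <= 0:
            raise InvalidConfigError("detection parameters must be positive")
        for name in ("fps", "min_separation_s", "stim_freq_hz"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidConfigError(f"{name} must be positive when given")
        if self.roi is not None:
            self.roi = tuple(int(v) for v in self.roi)
            if len(self.roi) != 4:
                raise InvalidConfigError("roi must be (top, left, height, width)")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise InvalidConfigError(f"unknown log level {self.log_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected, CLI overrides win."""
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise InvalidConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise InvalidConfigError(f"{path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def trace_config(self) -> TraceConfig:
        return TraceConfig(
            transform=PolarTransformConfig(
                radial_oversample=self.radial_oversample,
                angular_oversample=self.angular_oversample,
                kernel=self.kernel,
            ),
            reference=self.reference,
        )

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            threshold_mads=self.threshold_mads,
            baseline_window_s=self.baseline_window_s,
            min_separation_s=self.min_separation_s,
            stim_freq_hz=self.stim_freq_hz,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["roi"] is not None:
            d["roi"] = list(d["roi"])
        return d
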