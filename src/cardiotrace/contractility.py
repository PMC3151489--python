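"""Contraction traces, beat detection and contraction/relaxation metrics.

Each frame of a masked recording is summarized by the magnitude of its
polar Fourier transform (a rotation-covariant spectral descriptor of the
cell's interior arrangement).  The zero-lag Pearson correlation between a
frame's descriptor and a reference (resting) frame's descriptor yields a
per-frame similarity in [-1, 1]; ``contraction = 1 - similarity`` turns
beats into upward deflections.  Peaks of that trace are the contraction
events; their timing against the baseline gives beat rate, time to peak,
plateau duration and relaxation times.

The origin (DC) sample is excluded from the descriptor, and Pearson
normalization removes gain, so the trace is insensitive to global
illumination changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .errors import DegenerateDataError, InvalidArgumentError
from .frames import FrameStack, Mask, apply_mask
from .transform import PolarSpectrum, PolarTransformConfig, polar_fft

__all__ = [
    "TraceConfig",
    "DetectionConfig",
    "ContractionTrace",
    "ContractionEvent",
    "ContractionMetrics",
    "pearson_similarity",
    "spectral_similarity",
    "compute_trace",
    "detect_events",
    "summarize",
    "events_to_json",
]

EVENTS_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class TraceConfig:
    """How frames are turned into the similarity trace.

    ``reference`` selects the frame every other frame is correlated with:
    ``"first"`` (default) or ``"rest"``, the frame closest (mean absolute
    difference inside the mask) to the per-pixel temporal median, i.e. the
    most at-rest frame.
    """

    transform: PolarTransformConfig = field(default_factory=PolarTransformConfig)
    reference: str = "first"

    def __post_init__(self) -> None:
        if self.reference not in ("first", "rest"):
            raise InvalidArgumentError("reference must be 'first' or 'rest'")


@dataclass(frozen=True)
class DetectionConfig:
    """Beat-detection parameters.

    Peaks must exceed the running-median baseline by ``threshold_mads``
    robust noise units (MAD of the baseline-removed trace scaled by
    1.4826), and be separated by at least ``min_separation_s`` (default:
    half the stimulation period when the stimulation frequency is known,
    else 0.5 s).
    """

    threshold_mads: float = 5.0
    baseline_window_s: float = 2.0
    min_separation_s: float | None = None
    stim_freq_hz: float | None = None

    def min_separation(self) -> float:
        if self.min_separation_s is not None:
            return self.min_separation_s
        if self.stim_freq_hz:
            return 0.5 / self.stim_freq_hz
        return 0.5


@dataclass
class ContractionTrace:
    """Per-frame similarity with the reference frame's spectral descriptor."""

    similarity: np.ndarray
    fps: float
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.similarity = np.asarray(self.similarity, dtype=np.float64)
        if self.similarity.ndim != 1 or self.similarity.size == 0:
            raise InvalidArgumentError("similarity must be a non-empty 1-D array")
        if not self.fps > 0:
            raise InvalidArgumentError("fps must be positive")
        if not 0 <= self.reference_index < self.similarity.size:
            raise InvalidArgumentError("reference_index outside the trace")

    def __len__(self) -> int:
        return self.similarity.size

    @property
    def contraction(self) -> np.ndarray:
        """``1 - similarity``: contraction as an upward deflection in [0, 2]."""
        return 1.0 - self.similarity

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    @property
    def duration(self) -> float:
        return len(self) / self.fps

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.times,
                "similarity": self.similarity,
                "contraction": self.contraction,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        # fixed 9-significant-digit formatting keeps reruns byte-identical
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path: str | Path, fps: float | None = None) -> "ContractionTrace":
        df = pd.read_csv(path)
        if fps is None:
            dt = np.diff(df["time_s"].to_numpy())
            fps = 1.0 / float(np.median(dt)) if dt.size else 30.0
        sim = df["similarity"].to_numpy()
        ref = int(np.argmax(sim >= 1.0)) if np.any(sim >= 1.0) else 0
        return cls(similarity=sim, fps=fps, reference_index=ref)


@dataclass(frozen=True)
class ContractionEvent:
    """One detected beat on the contraction trace (frame indices)."""

    onset_frame: int
    peak_frame: int
    end_frame: int
    amplitude: float
    plateau_frames: int
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.onset_frame <= self.peak_frame <= self.end_frame:
            raise InvalidArgumentError("event frames must satisfy onset <= peak <= end")
        if not self.amplitude > 0:
            raise InvalidArgumentError("event amplitude must be positive")


@dataclass(frozen=True)
class ContractionMetrics:
    """Summary physiology numbers over the detected events.

    Durations are seconds; fields are ``None`` when no event (or no
    completed recovery) supports them.  ``beat_rate`` is events per second
    over the whole trace.
    """

    n_events: int
    beat_rate: float
    time_to_peak: float | None
    relaxation_time_50: float | None
    relaxation_time_90: float | None
    mean_amplitude: float | None
    plateau_duration: float | None


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag normalized (Pearson) correlation of two sample vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise InvalidArgumentError("sample vectors must have equal length")
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 samples to correlate")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise DegenerateDataError("zero-variance magnitude array cannot be correlated")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def spectral_similarity(spec_a: PolarSpectrum, spec_b: PolarSpectrum) -> float:
    """Similarity of two polar spectra: Pearson correlation of their
    magnitude descriptors (origin sample excluded)."""
    if spec_a.grid.N != spec_b.grid.N:
        raise InvalidArgumentError(
            f"spectra on different grids (N={spec_a.grid.N} vs N={spec_b.grid.N})"
        )
    return pearson_similarity(spec_a.feature_vector(), spec_b.feature_vector())


def _descriptor_matrix(stack: FrameStack, mask: Mask, config: TraceConfig) -> np.ndarray:
    feats = None
    for k in range(len(stack)):
        spec = polar_fft(apply_mask(stack.frames[k], mask), config.transform)
        v = spec.feature_vector()
        if feats is None:
            feats = np.empty((len(stack), v.size))
        feats[k] = v
    return feats


def _rest_frame_index(stack: FrameStack, mask: Mask) -> int:
    masked = stack.frames * mask.raster
    med = np.median(masked, axis=0)
    dev = np.abs(masked - med).mean(axis=(1, 2))
    return int(np.argmin(dev))


def compute_trace(stack: FrameStack, mask: Mask, config: TraceConfig | None = None) -> ContractionTrace:
    """Mask every frame, transform it, and correlate against the reference.

    Returns the per-frame similarity trace; ``similarity`` is exactly 1 at
    the reference frame, and a single-frame stack yields the trivial
    length-1 trace.
    """
    config = config or TraceConfig()
    if stack.frame_shape != mask.shape:
        raise InvalidArgumentError(
            f"mask shape {mask.shape} does not match frames {stack.frame_shape}"
        )
    feats = _descriptor_matrix(stack, mask, config)
    ref = 0 if config.reference == "first" else _rest_frame_index(stack, mask)
    centered = feats - feats.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if norms[ref] == 0:
        raise DegenerateDataError("reference frame has a zero-variance spectrum")
    bad = norms == 0
    norms[bad] = 1.0
    sim = (centered @ centered[ref]) / (norms * norms[ref])
    sim[bad] = 0.0
    sim = np.clip(sim, -1.0, 1.0)
    sim[ref] = 1.0
    return ContractionTrace(similarity=sim, fps=stack.fps, reference_index=ref)


def detect_events(trace: ContractionTrace, config: DetectionConfig | None = None) -> list[ContractionEvent]:
    """Find beats on the contraction trace.

    Baseline is a running median; the noise scale is the MAD of the
    baseline-removed trace (scaled to a Gaussian sigma).  Local maxima
    above ``baseline + threshold_mads * noise`` and separated by the
    minimum spacing are kept; each peak is then localized at the center of
    its >= 90%-amplitude plateau, and onset/end are the nearest crossings
    of ``baseline + 10%`` of the amplitude on either side.
    """
    config = config or DetectionConfig()
    if len(trace) < 3:
        raise InvalidArgumentError("need at least 3 frames to detect events")
    c = trace.contraction
    win = int(round(config.baseline_window_s * trace.fps))
    win = max(3, win + (1 - win % 2))  # odd window
    baseline = median_filter(c, size=min(win, len(c) + (1 - len(c) % 2)), mode="nearest")
    resid = c - baseline
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    distance = max(1, int(round(config.min_separation() * trace.fps)))
    peaks, _ = find_peaks(c, distance=distance)
    events: list[ContractionEvent] = []
    for p in peaks:
        base = float(baseline[p])
        amp = float(c[p] - base)
        if amp <= config.threshold_mads * noise or amp <= 0:
            continue
        # plateau: contiguous frames around p at >= 90% of the amplitude
        hi = base + 0.9 * amp
        lo_level = base + 0.1 * amp
        left = p
        while left > 0 and c[left - 1] >= hi:
            left -= 1
        right = p
        while right < len(c) - 1 and c[right + 1] >= hi:
            right += 1
        peak_frame = int(round((left + right) / 2.0))
        onset = left
        while onset > 0 and c[onset] > lo_level:
            onset -= 1
        end = right
        while end < len(c) - 1 and c[end] > lo_level:
            end += 1
        events.append(
            ContractionEvent(
                onset_frame=int(onset),
                peak_frame=peak_frame,
                end_frame=int(end),
                amplitude=amp,
                plateau_frames=int(right - left + 1),
                baseline=base,
            )
        )
    return events


def _recovery_time(c: np.ndarray, ev: ContractionEvent, fraction: float, fps: float) -> float | None:
    """Seconds from the peak until contraction first falls to
    ``baseline + fraction * amplitude``; None if it never does."""
    level = ev.baseline + fraction * ev.amplitude
    for j in range(ev.peak_frame, c.size):
        if c[j] <= level:
            return (j - ev.peak_frame) / fps
    return None


def summarize(trace: ContractionTrace, events: list[ContractionEvent]) -> ContractionMetrics:
    """Aggregate event timings into physiology metrics (seconds)."""
    n = len(events)
    rate = n / trace.duration
    if n == 0:
        return ContractionMetrics(0, rate, None, None, None, None, None)
    c = trace.contraction
    ttp = float(np.mean([(e.peak_frame - e.onset_frame) for e in events])) / trace.fps
    r50 = [t for e in events if (t := _recovery_time(c, e, 0.5, trace.fps)) is not None]
    r90 = [t for e in events if (t := _recovery_time(c, e, 0.1, trace.fps)) is not None]
    return ContractionMetrics(
        n_events=n,
        beat_rate=rate,
        time_to_peak=ttp,
        relaxation_time_50=float(np.mean(r50)) if r50 else None,
        relaxation_time_90=float(np.mean(r90)) if r90 else None,
        mean_amplitude=float(np.mean([e.amplitude for e in events])),
        plateau_duration=float(np.mean([e.plateau_frames for e in events])) / trace.fps,
    )


def events_to_json(events: list[ContractionEvent], metrics: ContractionMetrics, path: str | Path, fps: float) -> None:
    """Write per-event records and the metrics block as versioned JSON."""
    payload = {
        "schema_version": EVENTS_SCHEMA_VERSION,
        "fps": fps,
        "events": [
            {
                "onset_frame": e.onset_frame,
                "peak_frame": e.peak_frame,
                "end_frame": e.end_frame,
                "onset_s": e.onset_frame / fps,
                "peak_s": e.peak_frame / fps,
                "end_s": e.end_frame / fps,
                "amplitude": e.amplitude,
                "plateau_frames": e.plateau_frames,
                "baseline": e.baseline,
            }
            for e in events
        ],
        "metrics": {
            "n_events": metrics.n_events,
            "beat_rate_hz": metrics.beat_rate,
            "time_to_peak_s": metrics.time_to_peak,
            "relaxation_time_50_s": metrics.relaxation_time_50,
            "relaxation_time_90_s": metrics.relaxation_time_90,
            "mean_amplitude": metrics.mean_amplitude,
            "plateau_duration_s": metrics.plateau_duration,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
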