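"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* images are 2D arrays indexed ``[y, x]`` with the origin at the top-left
  pixel centre, x increasing rightward and y downward, 0-based;
* a displacement field has components ``u`` (along x) and ``v`` (along y),
  both in px/frame;
* physical calibration is carried as ``pixel_size_um`` (μm per pixel) and
  ``frame_rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSequence", "FlowField", "BeatTrace", "TimecoursePoint"]


@dataclass
class ImageSequence:
    """A regularly sampled stack of grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Scalar intensity frames.
    pixel_size_um : float
        Lateral calibration, μm per pixel.
    frame_rate_hz : float
        Acquisition rate in Hz.
    t_start_s : float
        Absolute time of the first frame within the experiment, seconds.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    t_start_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def times_s(self) -> np.ndarray:
        """Absolute time stamp of every frame."""
        return self.t_start_s + np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class FlowField:
    """Dense displacement between two consecutive frames.

    ``u`` and ``v`` are in px/frame; ``grad_strength`` is the squared spatial
    intensity-gradient magnitude of the source frame, used downstream as a
    confidence weight for smoothing.
    """

    u: np.ndarray
    v: np.ndarray
    grad_strength: np.ndarray

    def __post_init__(self) -> None:
        u, v, g = (np.asarray(a, dtype=float) for a in (self.u, self.v, self.grad_strength))
        if not (u.shape == v.shape == g.shape):
            raise ValueError("u, v, grad_strength must share a shape")
        if not (np.isfinite(u).all() and np.isfinite(v).all() and np.isfinite(g).all()):
            raise ValueError("flow components must be finite")
        if (g < 0).any():
            raise ValueError("grad_strength must be nonnegative")
        self.u, self.v, self.grad_strength = u, v, g

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class BeatTrace:
    """A regularly sampled scalar time series, the unit of spectral analysis.

    Typically the region-mean total volumetric strain of one burst.
    """

    values: np.ndarray
    sampling_rate_hz: float
    t_start_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz

    def times_s(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.n) / self.sampling_rate_hz


@dataclass
class TimecoursePoint:
    """One burst's summary statistics within a drug-response experiment."""

    t_min: float
    rate_hz: float
    amplitude_pp: float
    stage: str = ""
    quality: float = float("nan")
    sample_id: str = "s0"
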