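"""Strain-rate tensor and volumetric strain maps from dense flow fields.

The symmetric strain-rate tensor is the symmetric part of the displacement
gradient, eps = (grad(u) + grad(u)^T)/2, evaluated per frame pair in units
of 1/frame.  The volumetric strain rate is its trace — for the 2D sections
measured here, e_xx + e_yy — which equals the divergence of the displacement
field.  Rate maps are smoothed with a gradient-weighted Gaussian kernel
(normalized convolution), averaged over a region of interest, and integrated
across frames into the total volumetric strain trace used for beat analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator

from .core import BeatTrace, FlowField

__all__ = [
    "StrainMaps",
    "SmoothingSpec",
    "strain_tensor",
    "volumetric_strain_rate",
    "smooth_weighted",
    "integrate_strain",
    "ellipse_mask",
    "StrainMapper",
]


@dataclass
class StrainMaps:
    """Per-pixel strain-rate components for one frame pair (1/frame)."""

    e_xx: np.ndarray
    e_yy: np.ndarray
    e_xy: np.ndarray
    div: np.ndarray
    frame_index: int = 0


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing of rate maps, in physical units.

    ``weight_mode='gradient'`` weights each pixel by the flow field's
    squared-gradient confidence map; ``'uniform'`` reduces to a plain
    Gaussian filter.
    """

    sigma_um: float = 11.0
    weight_mode: str = "gradient"

    def __post_init__(self) -> None:
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be positive")
        if self.weight_mode not in ("gradient", "uniform"):
            raise ValueError("weight_mode must be 'gradient' or 'uniform'")


def strain_tensor(flow: FlowField, frame_index: int = 0) -> StrainMaps:
    """Central-difference strain-rate tensor of a flow field."""
    du_dy, du_dx = np.gradient(flow.u)
    dv_dy, dv_dx = np.gradient(flow.v)
    e_xx = du_dx
    e_yy = dv_dy
    e_xy = 0.5 * (du_dy + dv_dx)
    return StrainMaps(e_xx=e_xx, e_yy=e_yy, e_xy=e_xy, div=e_xx + e_yy,
                      frame_index=frame_index)


def volumetric_strain_rate(flow: FlowField) -> np.ndarray:
    """Divergence of the displacement field, i.e. the trace of the tensor."""
    return strain_tensor(flow).div


def smooth_weighted(
    field: np.ndarray,
    weights: np.ndarray | None,
    spec: SmoothingSpec,
    pixel_size_um: float,
) -> np.ndarray:
    """Gaussian smoothing with per-pixel confidence weights.

    Normalized convolution: ``G*(w·f) / G*(w)`` with a Gaussian of standard
    deviation ``sigma_um / pixel_size_um`` pixels.  Uniform weights reduce
    this exactly to plain Gaussian smoothing.
    """
    field = np.asarray(field, dtype=float)
    sigma_px = spec.sigma_um / pixel_size_um
    if spec.weight_mode == "uniform" or weights is None:
        return gaussian_filter(field, sigma_px, mode="nearest")
    w = np.asarray(weights, dtype=float)
    if w.shape != field.shape:
        raise ValueError("field and weights must share a shape")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("weights are all zero")
    num = gaussian_filter(w * field, sigma_px, mode="nearest")
    den = gaussian_filter(w, sigma_px, mode="nearest")
    tiny = np.finfo(float).tiny
    return num / np.maximum(den, tiny)


def integrate_strain(
    rate_series: np.ndarray,
    frame_rate_hz: float,
    t_start_s: float = 0.0,
    detrend: bool = False,
    label: str = "",
) -> BeatTrace:
    """Cumulative sum of per-frame region-mean strain rates → total strain.

    Eulerian accumulation: the trace value after frame k is the sum of the
    first k frame-to-frame volumetric strain rates (units of 1 — fractional
    volume change).  Optional linear detrend removes slow drift from
    accumulated flow bias.
    """
    rates = np.asarray(rate_series, dtype=float).ravel()
    if rates.size == 0:
        raise ValueError("rate series is empty")
    total = np.cumsum(rates)
    if detrend:
        t = np.arange(total.size, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, total, 1)
        total = total - (coef[0] + coef[1] * t)
    return BeatTrace(values=total, sampling_rate_hz=frame_rate_hz,
                     t_start_s=t_start_s, label=label)


def region_mean_series(maps: list[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Mean of each map over a boolean region mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("region mask is empty")
    return np.array([m[mask].mean() for m in maps])


def ellipse_mask(shape: tuple[int, int], center_px: tuple[float, float],
                 semi_axes_px: tuple[float, float]) -> np.ndarray:
    """Boolean elliptical ROI; center/axes in pixel units, (x, y) order."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cx, cy = center_px
    a, b = semi_axes_px
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


class StrainMapper(BaseEstimator):
    """Flow fields → smoothed volumetric-strain-rate maps and region traces.

    A stateless transformer: ``transform`` maps a list of
    :class:`~heartflow.core.FlowField` to smoothed divergence maps;
    ``trace`` additionally averages over a region mask and integrates to the
    total volumetric strain.
    """

    def __init__(self, sigma_um: float = 11.0, weight_mode: str = "gradient",
                 detrend: bool = False) -> None:
        self.sigma_um = sigma_um
        self.weight_mode = weight_mode
        self.detrend = detrend

    def _spec(self) -> SmoothingSpec:
        return SmoothingSpec(sigma_um=self.sigma_um, weight_mode=self.weight_mode)

    def fit(self, X=None, y=None) -> "StrainMapper":
        return self

    def transform(self, flows: list[FlowField], pixel_size_um: float = 1.0) -> list[np.ndarray]:
        spec = self._spec()
        return [
            smooth_weighted(volumetric_strain_rate(f), f.grad_strength, spec, pixel_size_um)
            for f in flows
        ]

    def trace(
        self,
        flows: list[FlowField],
        mask: np.ndarray,
        pixel_size_um: float,
        frame_rate_hz: float,
        t_start_s: float = 0.0,
        label: str = "",
    ) -> BeatTrace:
        maps = self.transform(flows, pixel_size_um)
        rates = region_mean_series(maps, mask)
        return integrate_strain(rates, frame_rate_hz, t_start_s=t_start_s,
                                detrend=self.detrend, label=label)
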