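"""Heartbeat rate and contraction amplitude from strain traces via the PSD.

For each burst, the power spectral density of the mean-removed total-strain
trace is computed (Hann-windowed periodogram by default).  The beat rate is
the location of the dominant PSD peak within a physiological search band,
refined below the bin width by parabolic interpolation of log-power.  The
contraction amplitude is recovered from the power concentrated at the
fundamental and its harmonics via Parseval's theorem: a sinusoid of
amplitude A carries power A²/2, so the peak-to-peak amplitude of the
band-limited beat reconstruction is

    amplitude_pp = 2 * sqrt(2 * sum of beat-line powers).

A peak-to-background quality ratio flags traces without clear periodicity.
Per-burst estimates are assembled into a drug-response time course,
normalized to the mean of the baseline (stage i) bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from .core import BeatTrace, TimecoursePoint

__all__ = [
    "PSDResult",
    "BeatEstimate",
    "compute_psd",
    "estimate_beat",
    "BeatEstimator",
    "classify_stages",
    "normalize_to_baseline",
    "BaselineNormalizer",
]


@dataclass
class PSDResult:
    """One-sided power spectral density of a burst trace."""

    frequencies: np.ndarray  # Hz
    power: np.ndarray  # density, units²/Hz (window-gain corrected)
    resolution_hz: float  # 1 / trace duration

    def __post_init__(self) -> None:
        if (self.power < 0).any():
            raise ValueError("PSD power must be nonnegative")


@dataclass
class BeatEstimate:
    """Beat rate and contraction amplitude extracted from one PSD."""

    rate_hz: float
    amplitude_pp: float
    n_harmonics_used: int
    quality: float  # peak power over median in-band power
    low_confidence: bool = False


def compute_psd(trace: BeatTrace, min_periods: float = 2.0,
                expected_rate_hz: float = 0.5, window: str = "hann") -> PSDResult:
    """Hann-windowed periodogram of the mean-removed trace.

    The trace must span at least ``min_periods`` of the slowest expected
    beat; the frequency resolution is the reciprocal burst duration.  With
    density scaling, integrating ``power * df`` across a spectral line
    recovers that component's time-domain power (A²/2 for a sinusoid of
    amplitude A), regardless of where the line falls between bins.
    """
    n = trace.n
    fs = trace.sampling_rate_hz
    n_min = int(np.ceil(min_periods / expected_rate_hz * fs))
    if n < max(n_min, 4):
        raise ValueError(
            f"trace of {n} samples is too short: need >= {max(n_min, 4)} samples "
            f"({min_periods} periods at {expected_rate_hz} Hz, fs={fs} Hz)"
        )
    x = trace.values - trace.values.mean()
    win = signal.get_window(window, n)
    freqs, pxx = signal.periodogram(x, fs=fs, window=win, detrend=False,
                                    scaling="density")
    return PSDResult(frequencies=freqs, power=pxx, resolution_hz=fs / n)


def _parabolic_refine(freqs: np.ndarray, power: np.ndarray, i: int) -> float:
    """Sub-bin peak location by parabola through log-power at i-1, i, i+1."""
    if i <= 0 or i >= power.size - 1:
        return freqs[i]
    with np.errstate(divide="ignore"):
        y = np.log(power[i - 1:i + 2])
    if not np.isfinite(y).all():
        return freqs[i]
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0 or abs(denom) < 1e-300:
        return freqs[i]
    shift = 0.5 * (y[0] - y[2]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return freqs[i] + shift * (freqs[1] - freqs[0])


def estimate_beat(
    psd: PSDResult,
    band_hz: tuple[float, float] = (0.5, 5.0),
    n_harmonics: int = 2,
    refine: bool = True,
    quality_threshold: float = 20.0,
) -> BeatEstimate:
    """Beat rate and peak-to-peak amplitude from one PSD.

    ``n_harmonics`` counts harmonics above the fundamental included in the
    Parseval amplitude sum (2 by default, i.e. lines at f, 2f, 3f).  The
    estimate is flagged low-confidence when the peak-to-background power
    ratio falls below ``quality_threshold``.
    """
    f, p = psd.frequencies, psd.power
    lo, hi = band_hz
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError(f"band {band_hz} Hz contains no PSD bins "
                         f"(range {f.min():.3g}-{f.max():.3g} Hz)")
    idx = np.flatnonzero(sel)
    i_peak = idx[np.argmax(p[idx])]
    rate = _parabolic_refine(f, p, i_peak) if refine else f[i_peak]
    rate = float(np.clip(rate, lo, hi))

    df = f[1] - f[0]
    half_width = 2  # Hann main lobe: sum bins within ±2 of each line
    total_power = 0.0
    nyq = f[-1]
    used = 0
    for k in range(1, n_harmonics + 2):
        fk = k * rate
        if fk > nyq:
            break
        j = int(round(fk / df))
        j0, j1 = max(j - half_width, 1), min(j + half_width, p.size - 1)
        total_power += float(p[j0:j1 + 1].sum() * df)
        used += 1
    amplitude_pp = 2.0 * np.sqrt(2.0 * total_power)

    background = float(np.median(p[idx]))
    quality = float(p[i_peak] / background) if background > 0 else np.inf
    if not np.isfinite(quality):
        quality = np.inf if p[i_peak] > 0 else 0.0
    return BeatEstimate(
        rate_hz=float(rate),
        amplitude_pp=float(amplitude_pp),
        n_harmonics_used=max(used - 1, 0),
        quality=quality,
        low_confidence=bool(quality < quality_threshold),
    )


class BeatEstimator(BaseEstimator):
    """PSD beat analysis as a scikit-learn style estimator.

    ``fit`` consumes one :class:`~heartflow.core.BeatTrace` and exposes the
    fitted attributes ``rate_hz_``, ``amplitude_pp_``, ``quality_`` and
    ``psd_``.
    """

    def __init__(self, band_hz: tuple[float, float] = (0.5, 5.0),
                 n_harmonics: int = 2, refine: bool = True,
                 window: str = "hann", quality_threshold: float = 20.0) -> None:
        self.band_hz = band_hz
        self.n_harmonics = n_harmonics
        self.refine = refine
        self.window = window
        self.quality_threshold = quality_threshold

    def fit(self, X: BeatTrace, y=None) -> "BeatEstimator":
        self.psd_ = compute_psd(X, expected_rate_hz=self.band_hz[0],
                                window=self.window)
        est = estimate_beat(self.psd_, band_hz=self.band_hz,
                            n_harmonics=self.n_harmonics, refine=self.refine,
                            quality_threshold=self.quality_threshold)
        self.rate_hz_ = est.rate_hz
        self.amplitude_pp_ = est.amplitude_pp
        self.quality_ = est.quality
        self.low_confidence_ = est.low_confidence
        self.estimate_ = est
        return self

    def fit_predict(self, X: BeatTrace, y=None) -> BeatEstimate:
        return self.fit(X).estimate_


def classify_stages(timestamps_min: np.ndarray,
                    stage_times_min: tuple[float, float, float, float]) -> list[str]:
    """Label burst timestamps i/ii/iii by half-open protocol intervals.

    Boundary timestamps belong to the later stage; the final boundary is
    inclusive.  Timestamps outside the protocol are labeled ``unknown`` with
    a warning.
    """
    t0, t1, t2, t3 = stage_times_min
    labels = []
    for t in np.asarray(timestamps_min, dtype=float).ravel():
        if t0 <= t < t1:
            labels.append("i")
        elif t1 <= t < t2:
            labels.append("ii")
        elif t2 <= t <= t3:
            labels.append("iii")
        else:
            warnings.warn(f"timestamp {t} min outside protocol stages", stacklevel=2)
            labels.append("unknown")
    return labels


def normalize_to_baseline(points: list[TimecoursePoint]) -> pd.DataFrame:
    """Per-burst estimates → normalized drug-response time course.

    Rates and amplitudes are expressed as a percentage of the stage-(i)
    mean of each sample.  When several samples (animals) are present the
    per-time-point mean and standard deviation across samples are added.
    Output is time-ordered regardless of input order.
    """
    if not points:
        raise ValueError("no time-course points given")
    df = pd.DataFrame(
        {
            "t_min": [p.t_min for p in points],
            "stage": [p.stage for p in points],
            "rate_hz": [p.rate_hz for p in points],
            "amplitude_pp": [p.amplitude_pp for p in points],
            "quality": [p.quality for p in points],
            "sample_id": [p.sample_id for p in points],
        }
    ).sort_values(["sample_id", "t_min"], kind="stable").reset_index(drop=True)

    base = df[df.stage == "i"].groupby("sample_id")[["rate_hz", "amplitude_pp"]].mean()
    if base.empty:
        raise ValueError("no stage-(i) bursts to define the baseline")
    missing = set(df.sample_id) - set(base.index)
    if missing:
        raise ValueError(f"samples without stage-(i) baseline bursts: {sorted(missing)}")
    df["rate_pct"] = 100.0 * df.rate_hz / df.sample_id.map(base.rate_hz).to_numpy()
    df["amplitude_pct"] = (
        100.0 * df.amplitude_pp / df.sample_id.map(base.amplitude_pp).to_numpy()
    )
    if df.sample_id.nunique() > 1:
        grp = df.groupby("t_min")
        df["rate_pct_mean"] = df.t_min.map(grp.rate_pct.mean())
        df["rate_pct_std"] = df.t_min.map(grp.rate_pct.std(ddof=1))
        df["amplitude_pct_mean"] = df.t_min.map(grp.amplitude_pct.mean())
        df["amplitude_pct_std"] = df.t_min.map(grp.amplitude_pct.std(ddof=1))
    return df


class BaselineNormalizer(BaseEstimator):
    """Learn stage-(i) baselines on ``fit``; normalize points on ``transform``."""

    def fit(self, X: list[TimecoursePoint], y=None) -> "BaselineNormalizer":
        base = [p for p in X if p.stage == "i"]
        if not base:
            raise ValueError("no stage-(i) bursts to define the baseline")
        self.baseline_rate_hz_ = float(np.mean([p.rate_hz for p in base]))
        self.baseline_amplitude_pp_ = float(np.mean([p.amplitude_pp for p in base]))
        return self

    def transform(self, X: list[TimecoursePoint]) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_min": [p.t_min for p in X],
                "stage": [p.stage for p in X],
                "rate_hz": [p.rate_hz for p in X],
                "amplitude_pp": [p.amplitude_pp for p in X],
            }
        ).sort_values("t_min", kind="stable").reset_index(drop=True)
        df["rate_pct"] = 100.0 * df.rate_hz / self.baseline_rate_hz_
        df["amplitude_pct"] = 100.0 * df.amplitude_pp / self.baseline_amplitude_pp_
        return df

    def fit_transform(self, X: list[TimecoursePoint], y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
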