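"""Synthetic two-chamber beating-heart phantoms with exact ground truth.

The phantom emulates bright-field/fluorescence time-lapse data of a larval
zebrafish heart imaged in bursts (by default 15 s at 20 Hz once per minute):
two elliptical chambers (atrium and ventricle) filled with band-limited
speckle texture pulse on a static speckle background.  Each chamber deforms
by an affine dilation about its own centre, so the displacement field, the
volumetric strain rate and the integrated total strain are all available in
closed form and serve as oracles for the estimation pipeline.

Deformation convention
----------------------
The rest geometry is the systolic (minimum-area) configuration.  The
instantaneous area of a chamber is ``rest_area * (1 + s(t))`` with

    s(t) = A(t) * (w(phi) - min w),   phi = 2*pi*f(t)*(t - t_ref) + offset,

where ``w`` is a zero-mean waveform with unit peak-to-peak excursion (raised
cosine by default, i.e. ``cos(phi)/2``), so ``s`` sweeps [0, A].  With
``A = 1`` the chamber area therefore doubles over a beat.  Frame-to-frame
(Eulerian) integration of the divergence of the displacement telescopes to
``ln(1 + s(t))``; :class:`GroundTruth` exposes both the area-fraction
amplitude ``A`` and the integrated-strain amplitude ``ln(1 + A)``.

A three-stage drug-response model modulates the beat frequency and amplitude
across the experiment: a baseline period, a drug period with a smooth rate
drop and an exponential amplitude decay toward a floor, and a washout period
relaxing toward a configured fraction of baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.special import expit

from .core import ImageSequence

__all__ = [
    "ChamberSpec",
    "BeatModel",
    "DrugResponseModel",
    "AcquisitionProtocol",
    "GroundTruth",
    "HeartPhantom",
    "raised_cosine",
    "render_frame",
    "generate_burst",
    "generate_experiment",
    "write_burst",
    "read_burst",
]


def raised_cosine(phi: np.ndarray | float) -> np.ndarray | float:
    """Zero-mean, unit peak-to-peak raised-cosine beat waveform.

    The zero-mean form of ``(1 + cos phi)/2``; a single spectral line, which
    makes the phantom's strain trace a pure tone.
    """
    return 0.5 * np.cos(phi)


@dataclass(frozen=True)
class ChamberSpec:
    """One elliptical heart chamber in image coordinates (μm)."""

    name: str
    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]  # (a, b) at rest (systolic minimum)
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes_um) <= 0:
            raise ValueError(f"chamber {self.name}: semi-axes must be positive")

    @property
    def rest_area_um2(self) -> float:
        a, b = self.semi_axes_um
        return math.pi * a * b


@dataclass(frozen=True)
class BeatModel:
    """Baseline beat: frequency, peak-to-peak strain, intra-beat waveform."""

    f0_hz: float = 2.5
    a0: float = 1.0  # baseline peak-to-peak area strain (fraction of rest area)
    waveform: Callable[[np.ndarray], np.ndarray] = raised_cosine

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0 must be positive")
        if not 0.0 <= self.a0 < 2.0:
            raise ValueError("a0 must lie in [0, 2)")

    def waveform_min(self) -> float:
        phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        return float(np.min(self.waveform(phi)))


@dataclass(frozen=True)
class DrugResponseModel:
    """Three-stage drug protocol modulating beat rate and amplitude.

    Stage (i) is drug-free baseline; at the start of stage (ii) the drug
    takes effect, dropping the rate by ``rate_drop_fraction`` (negative
    values model rate-increasing agonists) and decaying the amplitude
    exponentially toward ``amplitude_floor`` with time constant
    ``amplitude_decay_tau_min``; stage (iii) is washout, relaxing both
    toward ``recovery_fraction`` of baseline.
    """

    stage_times_min: tuple[float, float, float, float] = (0.0, 30.0, 90.0, 150.0)
    rate_drop_fraction: float = 0.48
    amplitude_floor: float = 0.3
    amplitude_decay_tau_min: float = 10.0
    recovery_fraction: float = 0.85

    def __post_init__(self) -> None:
        st = self.stage_times_min
        if len(st) != 4 or not all(b > a for a, b in zip(st, st[1:])):
            raise ValueError("stage_times_min must be 4 strictly increasing values")
        if not -1.0 < self.rate_drop_fraction < 1.0:
            raise ValueError("rate_drop_fraction must lie in (-1, 1)")
        if self.amplitude_decay_tau_min <= 0:
            raise ValueError("amplitude_decay_tau_min must be positive")

    def stage(self, t_min: float) -> str:
        t0, t1, t2, t3 = self.stage_times_min
        if t0 <= t_min < t1:
            return "i"
        if t1 <= t_min < t2:
            return "ii"
        if t2 <= t_min <= t3:
            return "iii"
        return "unknown"

    def params_at(self, t_min: float, beat: BeatModel) -> tuple[float, float]:
        """Instantaneous (beat rate Hz, peak-to-peak amplitude) at time t."""
        t0, t1, t2, t3 = self.stage_times_min
        tau = self.amplitude_decay_tau_min
        f0, a0 = beat.f0_hz, beat.a0
        if t_min < t1:
            return f0, a0
        f_plateau = f0 * (1.0 - self.rate_drop_fraction)
        if t_min < t2:
            g = 1.0 - math.exp(-(t_min - t1) / tau)
            return f0 + (f_plateau - f0) * g, (
                self.amplitude_floor + (a0 - self.amplitude_floor) * (1.0 - g)
            )
        # stage (iii): relax from end-of-(ii) values toward recovery*baseline
        g2 = 1.0 - math.exp(-(t2 - t1) / tau)
        f_end2 = f0 + (f_plateau - f0) * g2
        a_end2 = self.amplitude_floor + (a0 - self.amplitude_floor) * (1.0 - g2)
        f_rec, a_rec = self.recovery_fraction * f0, self.recovery_fraction * a0
        g3 = 1.0 - math.exp(-(t_min - t2) / tau)
        return f_rec + (f_end2 - f_rec) * (1.0 - g3), a_rec + (a_end2 - a_rec) * (1.0 - g3)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Burst acquisition settings mirroring the imaging protocol."""

    burst_duration_s: float = 15.0
    burst_interval_s: float = 60.0
    frame_rate_hz: float = 20.0
    pixel_size_um: float = 2.5
    shape: tuple[int, int] = (96, 96)  # (H, W); heart size in px is a free choice
    noise_sigma: float = 0.02
    noise_model: str = "gaussian"  # or "poisson"
    texture_grain_um: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.burst_duration_s * self.frame_rate_hz
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("burst_duration × frame_rate must be an integer ≥ 2")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")

    @property
    def frames_per_burst(self) -> int:
        return int(round(self.burst_duration_s * self.frame_rate_hz))


def default_chambers() -> tuple[ChamberSpec, ChamberSpec]:
    """Ventricle + atrium sized to fit the default 240 μm field of view."""
    return (
        ChamberSpec("ventricle", (155.0, 120.0), (40.0, 32.0), phase_offset=0.0),
        ChamberSpec("atrium", (62.0, 120.0), (24.0, 20.0), phase_offset=np.pi / 2),
    )


@dataclass
class GroundTruth:
    """Analytic per-burst truth, derived from the model — never estimated.

    ``scales[c, j]`` is the linear dilation factor k of chamber c at frame j,
    with chamber area ``rest_area * k²``.
    """

    chambers: tuple[ChamberSpec, ...]
    scales: np.ndarray  # (n_chambers, T)
    pixel_size_um: float
    frame_rate_hz: float
    t_start_s: float
    stage: str
    true_rate_hz: float
    true_area_strain_pp: float  # the burst's A: peak-to-peak fractional area change
    shape: tuple[int, int]

    @property
    def true_amplitude_pp(self) -> float:
        """Peak-to-peak of the analytic integrated volumetric strain, ln(1+A)."""
        return math.log1p(self.true_area_strain_pp)

    def _grids_px(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.shape
        y, x = np.mgrid[0:h, 0:w]
        return x.astype(float), y.astype(float)

    def chamber_mask(self, chamber_index: int, frame: int, shrink: float = 1.0) -> np.ndarray:
        """Boolean mask of the chamber at a frame; shrink<1 keeps the core."""
        ch = self.chambers[chamber_index]
        k = self.scales[chamber_index, frame]
        x, y = self._grids_px()
        cx, cy = (c / self.pixel_size_um for c in ch.center_um)
        a, b = (s / self.pixel_size_um * k * shrink for s in ch.semi_axes_um)
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0

    def displacement(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Analytic (u, v) in px/frame mapping frame → frame+1."""
        x, y = self._grids_px()
        u = np.zeros(self.shape)
        v = np.zeros(self.shape)
        for ci, ch in enumerate(self.chambers):
            k0 = self.scales[ci, frame]
            kappa = self.scales[ci, frame + 1] / k0
            inside = self.chamber_mask(ci, frame)
            cx, cy = (c / self.pixel_size_um for c in ch.center_um)
            u[inside] = (kappa - 1.0) * (x[inside] - cx)
            v[inside] = (kappa - 1.0) * (y[inside] - cy)
        return u, v

    def strain_rate_map(self, frame: int) -> np.ndarray:
        """Analytic divergence of the frame→frame+1 displacement (1/frame)."""
        out = np.zeros(self.shape)
        for ci in range(len(self.chambers)):
            kappa = self.scales[ci, frame + 1] / self.scales[ci, frame]
            out[self.chamber_mask(ci, frame)] = 2.0 * (kappa - 1.0)
        return out

    def region_rate_series(self, chamber_index: int) -> np.ndarray:
        """Per-frame true divergence inside the chamber (length T−1)."""
        k = self.scales[chamber_index]
        return 2.0 * (k[1:] / k[:-1] - 1.0)

    def integrated_strain(self, chamber_index: int) -> np.ndarray:
        """Analytic total volumetric strain ln(area(t)/area(0)), length T."""
        k = self.scales[chamber_index]
        return 2.0 * np.log(k / k[0])


class HeartPhantom:
    """Renders image sequences of the beating two-chamber phantom.

    Textures are drawn once from ``protocol.seed``; per-frame noise streams
    are keyed on (seed, time), so any frame or burst is reproducible in
    isolation and whole runs are bit-identical under a fixed seed.
    """

    def __init__(
        self,
        chambers: Sequence[ChamberSpec] | None = None,
        beat: BeatModel | None = None,
        drug: DrugResponseModel | None = None,
        protocol: AcquisitionProtocol | None = None,
        edge_um: float = 3.0,
    ) -> None:
        self.chambers = tuple(chambers) if chambers is not None else default_chambers()
        self.beat = beat or BeatModel()
        self.drug = drug
        self.protocol = protocol or AcquisitionProtocol()
        self.edge_um = edge_um
        self._wmin = self.beat.waveform_min()
        rng = np.random.default_rng(self.protocol.seed)
        grain_px = max(self.protocol.texture_grain_um / self.protocol.pixel_size_um, 0.8)
        self._bg_tex = self._speckle(rng, grain_px)
        self._ch_tex = [self._speckle(rng, grain_px) for _ in self.chambers]
        self._check_bounds()

    def _speckle(self, rng: np.random.Generator, grain_px: float) -> np.ndarray:
        f = gaussian_filter(rng.standard_normal(self.protocol.shape), grain_px)
        f /= max(f.std(), 1e-12)
        return np.clip(f, -2.5, 2.5) / 2.5

    def _check_bounds(self) -> None:
        h, w = self.protocol.shape
        ext_x = (w - 1) * self.protocol.pixel_size_um
        ext_y = (h - 1) * self.protocol.pixel_size_um
        k_max = math.sqrt(1.0 + self.beat.a0)
        for ch in self.chambers:
            (cx, cy), (a, b) = ch.center_um, ch.semi_axes_um
            if (cx - k_max * a < 0 or cx + k_max * a > ext_x
                    or cy - k_max * b < 0 or cy + k_max * b > ext_y):
                raise ValueError(
                    f"chamber '{ch.name}' exits image bounds at maximal dilation"
                )

    # -- kinematics ---------------------------------------------------------

    def _params_at(self, t_s: float) -> tuple[float, float]:
        if self.drug is None:
            return self.beat.f0_hz, self.beat.a0
        return self.drug.params_at(t_s / 60.0, self.beat)

    def _scale(self, ch: ChamberSpec, t_s: float, f_hz: float, amp: float,
               t_ref_s: float) -> float:
        phi = 2.0 * np.pi * f_hz * (t_s - t_ref_s) + ch.phase_offset
        s = amp * (float(self.beat.waveform(phi)) - self._wmin)
        return math.sqrt(1.0 + s)

    # -- rendering ----------------------------------------------------------

    def render_frame(
        self,
        t_s: float,
        *,
        f_hz: float | None = None,
        amp: float | None = None,
        t_ref_s: float = 0.0,
        noise: bool = True,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Render the phantom at absolute time ``t_s`` (seconds).

        ``f_hz``/``amp`` override the instantaneous beat parameters (used by
        burst generation, which freezes them at the burst start); otherwise
        they come from the drug model (or baseline).
        """
        if t_s < 0:
            raise ValueError("t must be nonnegative")
        if f_hz is None or amp is None:
            f_hz, amp = self._params_at(t_s)
        p = self.protocol
        h, w = p.shape
        y, x = np.mgrid[0:h, 0:w]
        x_um = x * p.pixel_size_um
        y_um = y * p.pixel_size_um
        img = 0.12 + 0.06 * self._bg_tex
        for ci, ch in enumerate(self.chambers):
            k = self._scale(ch, t_s, f_hz, amp, t_ref_s)
            cx, cy = ch.center_um
            a, b = ch.semi_axes_um
            rho = np.sqrt(((x_um - cx) / (k * a)) ** 2 + ((y_um - cy) / (k * b)) ** 2)
            m = expit(-(rho - 1.0) * k * min(a, b) / self.edge_um)
            # sample chamber texture at material (rest) coordinates
            xm = (cx + (x_um - cx) / k) / p.pixel_size_um
            ym = (cy + (y_um - cy) / k) / p.pixel_size_um
            tex = map_coordinates(self._ch_tex[ci], [ym, xm], order=1, mode="reflect")
            img = img + m * (0.55 + 0.30 * tex - img)
        if noise and p.noise_sigma > 0:
            if rng is None:
                rng = np.random.default_rng([p.seed, 7, int(round(t_s * 1e6)) % (1 << 31)])
            if p.noise_model == "gaussian":
                img = img + rng.normal(0.0, p.noise_sigma, img.shape)
            else:
                photons = 1.0 / p.noise_sigma**2
                img = rng.poisson(np.clip(img, 0, None) * photons) / photons
        return img

    # -- bursts and experiments --------------------------------------------

    def generate_burst(self, t_start_s: float = 0.0) -> tuple[ImageSequence, GroundTruth]:
        """One acquisition burst with beat parameters frozen at its start."""
        p = self.protocol
        f_hz, amp = self._params_at(t_start_s)
        n = p.frames_per_burst
        times = t_start_s + np.arange(n) / p.frame_rate_hz
        rng = np.random.default_rng([p.seed, 11, int(round(t_start_s * 1e3)) % (1 << 31)])
        frames = np.stack(
            [
                self.render_frame(t, f_hz=f_hz, amp=amp, t_ref_s=t_start_s, rng=rng)
                for t in times
            ]
        ).astype(np.float32)
        scales = np.array(
            [
                [self._scale(ch, t, f_hz, amp, t_start_s) for t in times]
                for ch in self.chambers
            ]
        )
        stage = self.drug.stage(t_start_s / 60.0) if self.drug is not None else "i"
        gt = GroundTruth(
            chambers=self.chambers,
            scales=scales,
            pixel_size_um=p.pixel_size_um,
            frame_rate_hz=p.frame_rate_hz,
            t_start_s=t_start_s,
            stage=stage,
            true_rate_hz=f_hz,
            true_area_strain_pp=amp,
            shape=p.shape,
        )
        seq = ImageSequence(
            frames=frames,
            pixel_size_um=p.pixel_size_um,
            frame_rate_hz=p.frame_rate_hz,
            t_start_s=t_start_s,
            meta={"stage": stage, "seed": p.seed},
        )
        return seq, gt

    def generate_experiment(
        self, duration_min: float | None = None, burst_interval_s: float | None = None
    ) -> list[tuple[ImageSequence, GroundTruth]]:
        """One burst every ``burst_interval_s`` across stages (i)–(iii)."""
        if self.drug is None:
            raise ValueError("generate_experiment requires a DrugResponseModel")
        interval = burst_interval_s or self.protocol.burst_interval_s
        duration_s = (duration_min if duration_min is not None
                      else self.drug.stage_times_min[-1]) * 60.0
        if duration_s > self.drug.stage_times_min[-1] * 60.0 + 1e-9:
            raise ValueError("requested duration exceeds the drug model's stages")
        starts = np.arange(0.0, duration_s, interval)
        return [self.generate_burst(t) for t in starts]


# -- module-level functional surface ---------------------------------------


def render_frame(
    chambers: Sequence[ChamberSpec],
    beat: BeatModel,
    protocol: AcquisitionProtocol,
    t_s: float,
    drug: DrugResponseModel | None = None,
    **kwargs,
) -> np.ndarray:
    return HeartPhantom(chambers, beat, drug, protocol).render_frame(t_s, **kwargs)


def generate_burst(
    chambers: Sequence[ChamberSpec] | None,
    beat: BeatModel | None,
    protocol: AcquisitionProtocol | None,
    t_start_s: float = 0.0,
    drug: DrugResponseModel | None = None,
) -> tuple[ImageSequence, GroundTruth]:
    return HeartPhantom(chambers, beat, drug, protocol).generate_burst(t_start_s)


def generate_experiment(
    chambers: Sequence[ChamberSpec] | None,
    beat: BeatModel | None,
    drug: DrugResponseModel,
    protocol: AcquisitionProtocol | None,
    **kwargs,
) -> list[tuple[ImageSequence, GroundTruth]]:
    return HeartPhantom(chambers, beat, drug, protocol).generate_experiment(**kwargs)


# -- persistence ------------------------------------------------------------


def write_burst(directory: str | Path, index: int, seq: ImageSequence,
                gt: GroundTruth | None = None) -> Path:
    """Write one burst as multi-page TIFF + JSON sidecar (+ truth row dict)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"burst_{index:04d}"
    tif = directory / f"{stem}.tif"
    tifffile.imwrite(tif, np.asarray(seq.frames, dtype=np.float32))
    sidecar = {
        "pixel_size_um": seq.pixel_size_um,
        "frame_rate_hz": seq.frame_rate_hz,
        "t_start_s": seq.t_start_s,
        "stage": seq.meta.get("stage", ""),
        "seed": seq.meta.get("seed"),
    }
    if gt is not None:
        sidecar["true_rate_hz"] = gt.true_rate_hz
        sidecar["true_amplitude_pp"] = gt.true_amplitude_pp
        sidecar["true_area_strain_pp"] = gt.true_area_strain_pp
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return tif


def read_burst(tif_path: str | Path) -> ImageSequence:
    """Load a burst TIFF with its JSON sidecar back into an ImageSequence."""
    import tifffile

    tif_path = Path(tif_path)
    sidecar_path = tif_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_um", "frame_rate_hz"):
        if key not in meta:
            raise KeyError(f"{sidecar_path}: missing required metadata field '{key}'")
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageSequence(
        frames=frames,
        pixel_size_um=meta["pixel_size_um"],
        frame_rate_hz=meta["frame_rate_hz"],
        t_start_s=meta.get("t_start_s", 0.0),
        meta=meta,
    )
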