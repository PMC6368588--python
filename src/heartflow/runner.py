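"""End-to-end orchestration: simulate phantoms, analyze bursts, report designs.

Configuration is a single YAML file; every run writes a JSON manifest
recording the config snapshot, package version, timestamps and SHA-256
checksums of all outputs, so deterministic configs reproduce bit-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, beatline, trapcalc
from .core import TimecoursePoint
from .hsflow import HSParams, flow_sequence
from .phantom import (
    AcquisitionProtocol,
    BeatModel,
    ChamberSpec,
    DrugResponseModel,
    HeartPhantom,
    read_burst,
    write_burst,
)
from .strainmap import StrainMapper, ellipse_mask

log = logging.getLogger("heartflow")

__all__ = ["load_config", "run_simulate", "run_analyze", "run_trapcalc", "run_recover"]


# -- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def _phantom_from_config(cfg: dict) -> HeartPhantom:
    beat = BeatModel(**cfg.get("beat", {}))
    drug = DrugResponseModel(**cfg["drug"]) if "drug" in cfg else None
    proto_kwargs = dict(cfg.get("protocol", {}))
    if "shape" in proto_kwargs:
        proto_kwargs["shape"] = tuple(proto_kwargs["shape"])
    if "stage_times_min" in (cfg.get("drug") or {}):
        pass
    protocol = AcquisitionProtocol(**proto_kwargs)
    chambers = None
    if "chambers" in cfg:
        chambers = [
            ChamberSpec(
                name=c["name"],
                center_um=tuple(c["center_um"]),
                semi_axes_um=tuple(c["semi_axes_um"]),
                phase_offset=float(c.get("phase_offset", 0.0)),
            )
            for c in cfg["chambers"]
        ]
    return HeartPhantom(chambers=chambers, beat=beat, drug=drug, protocol=protocol)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Run manifest written before and finalized after every command."""

    def __init__(self, out_dir: Path, command: str, config: dict) -> None:
        self.path = out_dir / "manifest.json"
        self.data = {
            "command": command,
            "version": __version__,
            "config": config,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {},
            "status": "running",
        }
        out_dir.mkdir(parents=True, exist_ok=True)
        self._write()

    def _write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, default=str))

    def add(self, path: Path) -> None:
        self.data["outputs"][path.name] = _sha256(path)

    def finalize(self) -> None:
        self.data["status"] = "done"
        self.data["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._write()


# -- commands ---------------------------------------------------------------


def run_simulate(cfg: dict, out_dir: str | Path) -> Path:
    """Generate a phantom dataset on disk: burst TIFFs, sidecars, truth CSV."""
    out_dir = Path(out_dir)
    manifest = Manifest(out_dir, "simulate", cfg)
    ph = _phantom_from_config(cfg)
    sim = cfg.get("simulate", {})
    if ph.drug is not None:
        bursts = ph.generate_experiment(
            duration_min=sim.get("duration_min"),
            burst_interval_s=sim.get("burst_interval_s"),
        )
    else:
        starts = np.arange(int(sim.get("n_bursts", 1))) * ph.protocol.burst_interval_s
        bursts = [ph.generate_burst(t) for t in starts]
    rows = []
    for i, (seq, gt) in enumerate(bursts):
        tif = write_burst(out_dir, i, seq, gt)
        manifest.add(tif)
        manifest.add(tif.with_suffix(".json"))
        rows.append(
            {
                "burst": i,
                "t_start_s": seq.t_start_s,
                "stage": gt.stage,
                "true_rate_hz": gt.true_rate_hz,
                "true_amplitude_pp": gt.true_amplitude_pp,
                "true_area_strain_pp": gt.true_area_strain_pp,
            }
        )
        log.info("simulate burst=%d stage=%s frames=%d", i, gt.stage, seq.n_frames)
    gt_csv = out_dir / "ground_truth.csv"
    pd.DataFrame(rows).to_csv(gt_csv, index=False)
    manifest.add(gt_csv)
    manifest.finalize()
    return out_dir


def _analysis_components(cfg: dict):
    ana = cfg.get("analyze", {})
    hs = HSParams(**ana.get("hs", {}))
    mapper = StrainMapper(
        sigma_um=ana.get("sigma_um", 11.0),
        weight_mode=ana.get("weight_mode", "gradient"),
        detrend=bool(ana.get("detrend", False)),
    )
    band = tuple(ana.get("band_hz", (0.5, 5.0)))
    est = beatline.BeatEstimator(band_hz=band, n_harmonics=int(ana.get("n_harmonics", 2)))
    return hs, mapper, est, ana


def _roi_mask(cfg: dict, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    roi = cfg.get("analyze", {}).get("roi")
    if roi is None:
        # default: central ellipse of the default ventricle geometry
        roi = {"center_um": (155.0, 120.0), "semi_axes_um": (24.0, 19.2)}
    center_px = tuple(c / pixel_size_um for c in roi["center_um"])
    axes_px = tuple(a / pixel_size_um for a in roi["semi_axes_um"])
    return ellipse_mask(shape, center_px, axes_px)


def run_analyze(cfg: dict, data_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Analyze a directory of burst TIFFs into a normalized time course."""
    import tifffile

    data_dir, out_dir = Path(data_dir), Path(out_dir)
    manifest = Manifest(out_dir, "analyze", cfg)
    hs, mapper, est, ana = _analysis_components(cfg)
    tifs = sorted(data_dir.glob("burst_*.tif"))
    if not tifs:
        raise FileNotFoundError(f"no burst_*.tif files under {data_dir}")
    points: list[TimecoursePoint] = []
    save_maps = bool(ana.get("save_strain_maps", False))
    for tif in tifs:
        try:
            seq = read_burst(tif)
        except (ValueError, OSError) as exc:
            raise OSError(f"corrupt or unreadable TIFF {tif}: {exc}") from exc
        flows = flow_sequence(seq, hs)
        if ana.get("save_flows", False):  # opt-in: flow stacks are large
            from .hsflow import save_flow

            flow_dir = out_dir / f"{tif.stem}_flow"
            flow_dir.mkdir(parents=True, exist_ok=True)
            for k, fl in enumerate(flows):
                save_flow(flow_dir / f"flow_{k:04d}.npz", fl)
        if ana.get("flow_figure", False):
            for p in _flow_figure(seq, flows, out_dir, tif.stem):
                manifest.add(p)
        mask = _roi_mask(cfg, seq.shape, seq.pixel_size_um)
        maps = mapper.transform(flows, seq.pixel_size_um)
        if save_maps:
            map_path = out_dir / f"{tif.stem}_strainrate.tif"
            tifffile.imwrite(map_path, np.stack(maps).astype(np.float32))
            manifest.add(map_path)
        from .strainmap import integrate_strain, region_mean_series

        rates = region_mean_series(maps, mask)
        trace = integrate_strain(rates, seq.frame_rate_hz, t_start_s=seq.t_start_s,
                                 detrend=mapper.detrend)
        trace_csv = out_dir / f"{tif.stem}_trace.csv"
        pd.DataFrame(
            {
                "frame": np.arange(trace.n),
                "time_s": trace.times_s(),
                "strain": trace.values,
            }
        ).to_csv(trace_csv, index=False)
        manifest.add(trace_csv)
        est.fit(trace)
        stage = seq.meta.get("stage", "")
        points.append(
            TimecoursePoint(
                t_min=seq.t_start_s / 60.0,
                rate_hz=est.rate_hz_,
                amplitude_pp=est.amplitude_pp_,
                stage=stage,
                quality=est.quality_,
            )
        )
        log.info("analyze burst=%s stage=%s frames=%d rate=%.3f",
                 tif.stem, stage, seq.n_frames, est.rate_hz_)

    if any(p.stage == "i" for p in points):
        tc = beatline.normalize_to_baseline(points)
    else:
        log.warning("no stage-(i) bursts: writing unnormalized time course")
        tc = pd.DataFrame(
            {
                "t_min": [p.t_min for p in points],
                "stage": [p.stage for p in points],
                "rate_hz": [p.rate_hz for p in points],
                "amplitude_pp": [p.amplitude_pp for p in points],
                "quality": [p.quality for p in points],
            }
        )
    tc_csv = out_dir / "timecourse.csv"
    tc.to_csv(tc_csv, index=False)
    manifest.add(tc_csv)
    if ana.get("figures", True):
        for p in _figures(tc, out_dir):
            manifest.add(p)
    manifest.finalize()
    return tc


def _flow_figure(seq, flows, out_dir: Path, stem: str, frame: int = 0) -> list[Path]:
    """Velocity arrow plot of one frame pair over the source image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f = flows[frame]
    step = max(1, min(f.shape) // 24)
    y, x = np.mgrid[0:f.shape[0]:step, 0:f.shape[1]:step]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(seq.frames[frame], cmap="gray")
    ax.quiver(x, y, f.u[::step, ::step], f.v[::step, ::step],
              color="yellow", angles="xy", scale_units="xy", scale=0.2)
    ax.set_axis_off()
    p = out_dir / f"{stem}_flow.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return [p]


def _figures(tc: pd.DataFrame, out_dir: Path) -> list[Path]:
    """Time-course figures (artifacts only; numeric tables are the test surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for col, name in (("rate_pct", "rate"), ("amplitude_pct", "amplitude")):
        if col not in tc.columns:
            continue
        fig, ax = plt.subplots(figsize=(6, 3.2))
        ax.plot(tc.t_min, tc[col], "o-", ms=3)
        ax.set_xlabel("time (min)")
        ax.set_ylabel(f"{name} (% of baseline)")
        ax.axhline(100.0, color="0.7", lw=0.8)
        fig.tight_layout()
        p = out_dir / f"timecourse_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def run_trapcalc(cfg: dict) -> dict[str, float]:
    """Acoustic-trap / perfusion design report from a config mapping."""
    try:
        td = trapcalc.TransducerSpec(**cfg.get("transducer", {}))
        md = trapcalc.MediumSpec(**cfg.get("medium", {}))
        ch = trapcalc.PerfusionChamber(**cfg.get("chamber", {}))
    except TypeError as exc:
        raise ValueError(f"invalid trapcalc config: {exc}") from exc
    report = trapcalc.design_report(td, md, ch)
    if "pressure_amplitude_mpa" in cfg:
        report["focal_intensity_w_cm2"] = trapcalc.plane_wave_intensity(
            cfg["pressure_amplitude_mpa"], md
        )
    return report


def format_report(report: dict[str, float]) -> str:
    lines = ["acoustic trap / perfusion design report"]
    for key, val in report.items():
        name, _, unit = key.rpartition("_") if key[-1].isdigit() else (key, "", "")
        lines.append(f"  {key:30s} {val:.6g}")
    return "\n".join(lines)


def run_recover(cfg: dict, out_dir: str | Path) -> pd.DataFrame:
    """Phantom round trip: simulate in memory, analyze, report truth vs estimate."""
    out_dir = Path(out_dir)
    manifest = Manifest(out_dir, "recover", cfg)
    ph = _phantom_from_config(cfg)
    hs, mapper, est, _ = _analysis_components(cfg)
    sim = cfg.get("simulate", {})
    if ph.drug is not None:
        bursts = ph.generate_experiment(
            duration_min=sim.get("duration_min"),
            burst_interval_s=sim.get("burst_interval_s"),
        )
    else:
        bursts = [ph.generate_burst(0.0)]
    rows = []
    for i, (seq, gt) in enumerate(bursts):
        flows = flow_sequence(seq, hs)
        mask = gt.chamber_mask(0, 0, shrink=0.6)
        trace = mapper.trace(flows, mask, seq.pixel_size_um, seq.frame_rate_hz)
        est.fit(trace)
        rows.append(
            {
                "burst": i,
                "t_min": seq.t_start_s / 60.0,
                "stage": gt.stage,
                "true_rate_hz": gt.true_rate_hz,
                "est_rate_hz": est.rate_hz_,
                "true_amplitude_pp": gt.true_amplitude_pp,
                "est_amplitude_pp": est.amplitude_pp_,
                "quality": est.quality_,
            }
        )
        log.info("recover burst=%d stage=%s frames=%d", i, gt.stage, seq.n_frames)
    df = pd.DataFrame(rows)
    csv = out_dir / "recovery.csv"
    df.to_csv(csv, index=False)
    manifest.add(csv)
    manifest.finalize()
    return df
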