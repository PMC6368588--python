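# heartflow

Quantitative cardiac contractility analysis for time-lapse microscopy of
small beating hearts (e.g. larval zebrafish imaged by light-sheet
microscopy), together with the design arithmetic for the acoustic-trap /
perfusion rig that holds and doses the animal.

Given bursts of 2D grayscale frames (with μm/px and Hz calibration), the
pipeline:

1. estimates dense inter-frame displacements **u** with the Horn–Schunck
   variational method (brightness constancy + global smoothness,
   coarse-to-fine pyramid for larger motions);
2. maps them to the strain-rate tensor ε = ½(∇u + (∇u)ᵀ) and the volumetric
   strain rate ∇·**u** = tr ε (1/frame), smoothed by a gradient-weighted
   11 μm Gaussian (normalized convolution);
3. integrates the region-mean rate across frames into the total volumetric
   strain trace of a chamber;
4. extracts the beat rate (PSD peak, sub-bin refined) and the contraction
   amplitude (peak-to-peak of the fundamental + harmonics reconstruction,
   via Parseval) from each burst;
5. assembles bursts into three-stage drug-response time courses normalized
   to the pre-drug baseline.

A synthetic two-chamber beating-heart phantom (`heartflow.phantom`)
generates image sequences with *exact* analytic displacement, strain and
beat-parameter ground truth — including a verapamil-like scenario (smooth
48 % rate drop, exponential amplitude decay, partial washout recovery) —
and is the basis of the end-to-end validation. Closed-form calculators
(`heartflow.trapcalc`) reproduce the printed physics of a confocal
dual-transducer ultrasound trap and its perfusion chamber.

## Worked example

Analyze one synthetic burst (15 s at 20 Hz, beat 2.5 Hz, peak-to-peak area
strain A₀ = 0.5) and recover its beat parameters:

```python
from heartflow import (HeartPhantom, BeatModel, AcquisitionProtocol,
                       flow_sequence, StrainMapper, BeatEstimator)

phantom = HeartPhantom(beat=BeatModel(f0_hz=2.5, a0=0.5),
                       protocol=AcquisitionProtocol(seed=1))
seq, truth = phantom.generate_burst(0.0)          # 300 frames, 96×96 px
flows = flow_sequence(seq)                        # 299 fields, px/frame
mask = truth.chamber_mask(0, 0, shrink=0.6)       # central ventricle ROI
trace = StrainMapper().trace(flows, mask, seq.pixel_size_um, seq.frame_rate_hz)
beat = BeatEstimator().fit(trace)
print(f"rate {beat.rate_hz_:.3f} Hz (true {truth.true_rate_hz})")
print(f"amplitude {beat.amplitude_pp_:.3f} (true {truth.true_amplitude_pp:.3f})")
```

prints

```
rate 2.501 Hz (true 2.5)
amplitude 0.359 (true 0.405)
```

The rate is recovered far inside one frequency bin (1/15 Hz ≈ 0.067 Hz for
a 15 s burst). The amplitude is the peak-to-peak of the *integrated*
volumetric strain, whose analytic value for area strain A is ln(1 + A)
(= 0.405 for A = 0.5); the ~5–10 % shortfall is the systematic attenuation
of regularized flow plus smoothing (see `docs/methods.md`).

The trap design report:

```
$ heartflow trapcalc
acoustic trap / perfusion design report
  sound_speed_m_s                1488.36
  density_kg_m3                  997.483
  wavelength_mm                  0.992239
  f_number                       0.8
  resonator_axial_length_mm      32
  beam_diameter_6db_mm           1.11925
  washout_tau_min                2.875
  focal_intensity_w_cm2          22.6457
```

i.e. a 20 mm aperture / 16 mm focal-radius bowl at 1.5 MHz in 22 °C water
gives an f-number of 0.8, a ~1 mm wavelength, a 1.12 mm −6 dB focal beam,
a 32 mm confocal resonator, and 22.6 W/cm² focal intensity at 0.82 MPa;
the 57.5 mL chamber flushed at 20 mL/min washes out drugs with a
2.875 min time constant.

Other commands: `heartflow simulate` (write a phantom dataset as
multi-page TIFF bursts + JSON sidecars + ground-truth CSV),
`heartflow analyze` (full pipeline over a burst directory →
`timecourse.csv`, trace CSVs, figures), `heartflow recover` (in-memory
phantom round trip) — all driven by a YAML config and recorded in a
checksummed run manifest.

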