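# Methods

`heartflow` quantifies cardiac contractility from 2D time-lapse image
sequences of a beating larval-zebrafish-style heart, and provides the
supporting pieces needed to validate and design such an experiment: a
synthetic beating-heart phantom with exact ground truth, and closed-form
calculators for the acoustic trap and perfusion hardware that holds and
doses the animal.

## Analysis pipeline

### Optical flow (`hsflow`)

Displacements between consecutive frames are estimated with the
Horn–Schunck variational method: minimize

    E(u, v) = Σ (I_x u + I_y v + I_t)² + α² Σ_edges (Δu)² + (Δv)²

over the dense per-pixel field (u, v) in px/frame. Spatial gradients are
central differences averaged over the two frames; the temporal gradient is
the frame difference. The smoothness discretization is edge-based
(4-neighborhood), and the quadratic is minimized by red–black Gauss–Seidel
sweeps that solve the exact 2×2 per-pixel system for one checkerboard colour
at a time. This scheme was chosen over damped Jacobi because each half-sweep
is an exact block coordinate-descent step, which guarantees the objective is
non-increasing at every iteration — a property the test suite checks
directly.

Tunable parameters (all in `HSParams`):

- `alpha` (default **0.1**, intensity·px units, for images scaled to ~[0, 1]):
  smoothness weight. The value was calibrated so that sub-pixel rigid
  translations of speckle images are recovered to better than 0.1 px;
  larger values over-smooth the dilation fields of small chambers.
- `max_iter` 200 / `tol` 1e-3 px: iteration stops when the mean per-pixel
  update |Δu|+|Δv| falls below `tol`.
- `pyramid_levels` 2, `pyramid_scale` 0.5: coarse-to-fine estimation.
  The linearized data term is only valid for motions ≲1 px; at 20 Hz a
  vigorously beating ventricle moves up to ~2–3 px/frame at its wall, so the
  pyramid is on by default. It can be disabled (`pyramid_levels=1`) for
  strictly single-scale behaviour.

Each flow field carries `grad_strength = I_x² + I_y²`, the squared spatial
gradient magnitude. The flow is well constrained where gradients are strong,
so this map is reused downstream as a smoothing weight. Squared magnitude
(rather than magnitude) was chosen because it is the natural weight of the
data term's normal equations; the choice is configurable at the smoothing
step.

### Strain mapping (`strainmap`)

The strain-rate tensor is the symmetric displacement-gradient,
ε = ½(∇u + (∇u)ᵀ), by central differences; the volumetric strain rate is its
trace, equal to the divergence ∇·u, in 1/frame. Because the data are 2D
sections, the implemented trace is e_xx + e_yy — the 2D restriction of the
3D volumetric strain.

Rate maps are smoothed by normalized convolution,
`G ⊛ (w·field) / G ⊛ w`, with a Gaussian of standard deviation **11 μm**
(converted to pixels via the sequence's calibration) and weights w from the
flow's `grad_strength`. Uniform weights reduce exactly to plain Gaussian
smoothing. The 11 μm default suits hearts of the default phantom's scale
(chamber semi-axes 20–40 μm); for smaller structures the kernel should be
scaled down proportionally, otherwise boundary leakage biases region means
toward zero (the half-size test phantom uses 6 μm).

The region-mean smoothed rate of each frame pair is accumulated by a
cumulative sum (Eulerian, fixed-pixel integration — no material tracking)
into the total volumetric strain trace. Smoothing precedes region
averaging. An optional per-burst linear detrend (off by default) removes
the slow drift that integration of any small flow bias produces; the
spectral beat analysis is insensitive to such drift, so the default leaves
traces untouched.

### Beat extraction (`beatline`)

Each burst's mean-removed strain trace is analyzed with a Hann-windowed
periodogram (density scaling). The beat rate is the PSD argmax within a
search band (default **0.5–5 Hz**, covering larval zebrafish rates),
refined below the bin width (1/duration = 1/15 Hz for a 15 s burst) by
parabolic interpolation of log-power; a raw-bin mode is available.

The contraction amplitude is defined through Parseval's theorem: summing
`power·df` across the spectral lines at the fundamental and its first
`n_harmonics` (default 2) harmonics gives the beat component's time-domain
power P, and

    amplitude_pp = 2 √(2 P)

is the peak-to-peak excursion of the band-limited beat reconstruction
(exact for a pure tone; verified to <0.1 % on tones at arbitrary
inter-bin frequencies). Line power is collected over ±2 bins per harmonic
(the Hann main lobe). This mapping from spectral power to a peak-to-peak
strain is the package's own explicit convention.

A peak-to-background quality ratio (peak power / median in-band power)
flags unreliable estimates; the default threshold of 20 cleanly separates
white-noise traces (ratio ≈ 7 for ~70-bin bands) from genuine beats
(ratios ≫ 100).

Per-burst estimates are assembled into a three-stage drug-response time
course: bursts are labeled i/ii/iii by half-open protocol intervals
(boundaries belong to the later stage), rates and amplitudes are expressed
as a percentage of the stage-(i) mean per sample, and when several samples
are present the per-time mean ± standard deviation across samples is added.

## Synthetic phantom (`phantom`)

The phantom emulates the target acquisition: two elliptical chambers
(ventricle and atrium, the atrium phase-advanced by π/2) filled with
band-limited speckle on a static speckle background, imaged in **15 s
bursts at 20 Hz once per minute** (all configurable). Each chamber deforms
by affine dilation about its centre, chosen because it yields closed-form
displacement and divergence fields for oracle tests.

Strain convention: the rest geometry is the systolic minimum, and the
instantaneous area is `rest_area · (1 + s(t))` with `s = A·(w(φ) − min w)`
sweeping [0, A]; the default waveform is a raised cosine, making the area
trace a single spectral line. With A = 1 the chamber area doubles over a
beat. Frame-to-frame Eulerian integration of the divergence telescopes to
`ln(1 + s(t))`, so the ground-truth amplitude for the *integrated-strain*
measurand is `ln(1 + A)` (0.69 for A = 1); both this and the area-fraction
A are exposed by `GroundTruth`. A consequence worth noting when reading
normalized time courses: amplitude percentages are ratios of `ln(1 + A)`,
which compresses them relative to ratios of A (an A drop from 1.0 to 0.3
reads as ~38 %, not 30 %).

The three-stage drug model defaults encode the verapamil scenario: baseline
0–30 min; drug 30–90 min with the rate dropping smoothly by 48 % and the
amplitude decaying exponentially (τ = 10 min, a plausible onset scale for
a ~2 h protocol; the floor 0.3 mirrors the reported ~50 %→30 % contraction
drop) toward its floor; washout 90–150 min relaxing toward 85 % of
baseline (partial recovery). A negative `rate_drop_fraction` (−0.07)
models a norepinephrine-like rate increase. Baseline beat: 2.5 Hz, A = 1.

Image geometry is a free choice (no magnification is prescribed): 96×96 px
at 2.5 μm/px (240 μm field), ventricle semi-axes 40×32 μm (32 px across),
speckle grain 6 μm, additive Gaussian noise σ = 0.02 on ~[0, 1] intensities
(Poisson optional). Noise streams are keyed on (seed, burst, frame), so
fixed seeds give bit-identical datasets.

What the phantom does **not** emulate: out-of-plane motion and 3D chamber
geometry, blood-cell flow inside chambers, translation/rotation of the
whole heart, photobleaching, or non-affine wall deformation. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under ideal 2D kinematics, not robustness to every feature of live-animal
data.

## Design calculators (`trapcalc`)

Pure closed-form functions: wavelength λ = c/f; f-number = focal
radius / aperture; confocal resonator length = 2 × focal radius; −6 dB
focal beam diameter = 1.41·λ·f# (standard focused-piston approximation);
plane-wave intensity I = p²/(2ρc); apparent weight of a submerged sphere
(ρ_s − ρ_f)(π/6)d³g as the minimum levitation force; well-mixed washout
C(t) = C₀e^(−t/τ) with τ = V/Q (optional transport lag); and the
resource-equation sample-size rule (E = N − k, 10 ≤ E ≤ 20). Water
properties come from Marczak's sound-speed polynomial and Kell's density
formula at the chamber temperature (default 22 °C). Note the apparent
weight of a 500 μm soda-lime glass sphere (ρ ≈ 2500 kg/m³) is ~1 μN; trap
forces quoted as "at least 5 μN" elsewhere imply a different density or
size convention, so the calculator reports the formula value only.

## Numerical and scale choices

- Problem sizes: unit tests use a half-size phantom (64×64 px, 5 s bursts);
  the end-to-end acceptance tests and the acceptance script run the full
  96×96 px, 15 s/20 Hz protocol, with the staged experiment sampled at one
  burst per 10 min across the 150 min protocol.
- Boundary handling: replicate padding for derivatives and warping; flow
  invariants are asserted on the interior (≥3 px margin).
- Degenerate inputs: identical frames yield exactly zero flow; featureless
  frames yield zero flow (smoothness term alone); all-zero smoothing
  weights, empty ROIs, too-short traces, and out-of-protocol timestamps
  raise descriptive errors (the last one warns and labels `unknown`).
- Determinism: every stochastic component draws from
  `numpy.random.default_rng` seeded from explicit integers; rerunning a
  config reproduces byte-identical outputs (checksummed in run manifests).

## Known limitations

- Flow-derived amplitudes carry a systematic 5–10 % underestimate (HS
  regularization plus smoothing leakage); rate estimates are essentially
  exact (≪ one frequency bin on phantoms).
- The Eulerian integrated strain measures ln-volume change; comparisons
  against fractional-volume conventions must use `ln(1 + A)`.
- The quality metric is a proxy for rhythmicity; it is not an arrhythmia
  classifier.
- 2D sections only: through-plane strain is invisible, so "volumetric"
  strain here is the 2D trace restriction.
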