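# Methods

## The physical model

A sneeze or cough expels a cloud of secretion droplets and droplet nuclei
with high initial momentum. Air friction decelerates the cloud until its
forward speed falls to the level of the ambient indoor airflow, after
which transport is diffusion- and convection-dominated. The package
models the horizontal velocity of the cloud's advancing margin (the
*front line*) as an exponential decay

    Vh(t) = A exp(-k t) + c

with amplitude `A` (cm/s), decay rate `k` (1/s), and offset `c` (cm/s).
The offset is the residual drift the front settles onto: ~0 in a calm
room, or the speed of a directed ventilation current. Two reference
coefficient sets are built in: a sneeze (`A = 1500`, `k = 22`, `c = 0`)
and a cough recorded in a ventilated room (`A = 1100`, `k = 32`,
`c = 27`).

Two closed-form quantities follow:

- **Momentum-loss time.** With `v*` the ambient convection speed
  (default 15 cm/s, the accepted mean for indoor natural convection;
  30 cm/s for the ventilated cough room),
  `t* = (1/k) ln(A / (v* - c))`. This gives 0.209 s for the sneeze model
  and 0.18 s for the cough model.
- **Direct reach.** The momentum-driven displacement between `t0` and
  `t1` is the integral of `Vh`:
  `reach = h0 + (A/k)(e^{-k t0} - e^{-k t1}) + c (t1 - t0)`.
  The anchor `(t0, h0)` is an explicit parameter: a velocity-only fit
  determines the model up to an unknown spatial offset, so the reach
  depends on where the model is anchored. With `t0 = 0, h0 = 0` the
  sneeze model's total momentum-driven displacement is `A/k ≈ 68 cm`;
  the cough model integrated over its usable window 0.03–0.18 s gives
  ≈ 17 cm. Reported literature reaches for comparable events (~84 cm
  and ~30 cm) imply a non-zero anchor that is not recoverable from the
  velocity model alone; the package exposes `h_anchor` rather than
  guessing one.

## Pipeline

1. **Acquisition** — either a recorded stack of 8-bit grayscale frames
   (PNG/TIFF, default 1/300 s interval, 640×400 px) with a spatial
   calibration (cm/px, mouth position), or the synthetic generator below.
2. **Optional enhancement** — global binarization (Otsu or manual
   threshold). This mirrors the binary enhancement used to make faint
   particles visible in video stills; tracking runs on the original
   graylevels by default because correlation on graylevels preserves
   subpixel information.
3. **Vector analysis** — each frame pair is divided into 21×21 px
   interrogation windows (≈ 4.4 cm at the default calibration of
   4.4/21 cm/px). Each window is located in the next frame by
   zero-normalized cross-correlation (ZNCC) inside a ±15 px search
   region, refined to subpixel precision, and validated (below).
   Velocities are `displacement × pixel_size / dt`; a 1/10 px
   localization error corresponds to ≈ 6.3 cm/s at the default
   calibration and frame rate.
4. **Front-line reduction** — vectors falling faster than the Stokes
   settling velocity of a 300 µm water droplet (≈ 273 cm/s) are excluded
   as large ballistic droplets; per frame, the remaining valid vector
   with the largest horizontal distance `h ≥ 0` from the mouth is the
   front-line point `(t, h, Vh)`. An optional top-quantile average is
   available instead of the single farthest vector.
5. **Model fit** — nonlinear least squares of `A e^{-kt} + c`,
   initialized by linear regression of `ln(Vh - c0)` on `t`. The offset
   can be left free, pinned to a value, or pinned to the mean of the
   final three points (`"plateau"`). Unweighted least squares is the
   default; a soft-L1 robust loss is available for outlier-prone series.
6. **Kinematic estimates** — closed-form momentum-loss time and reach.

## Vector-analysis details

- **Correlation.** ZNCC (mean-subtracted, variance-normalized per
  placement), values in [-1, 1]; FFT-accelerated via
  `skimage.feature.match_template` and verified in the tests against a
  brute-force spatial implementation to 1e-8. A zero-variance template is
  flagged invalid rather than raising.
- **Grid placement.** Windows are placed so that the full search margin
  (half-window + search radius) fits inside the frame. A clamped search
  region would put small displacements on the border of the correlation
  surface, where subpixel refinement is impossible.
- **Subpixel peak.** Per-axis three-point Gaussian fit,
  `δ = (ln R₋ - ln R₊) / (2 ln R₋ - 4 ln R₀ + 2 ln R₊)`; the three values
  are min-shifted to positive (+1e-6) before the log when necessary, and
  a non-finite or out-of-range (|δ| ≥ 1) correction falls back to 0. A
  peak on the surface border keeps its integer location and is flagged
  reduced-precision. On adequately seeded noiseless pairs the recovery
  RMS over imposed shifts of 0.1–0.9 px is ≈ 0.02 px; the quoted 1/10 px
  figure is a conservative bound that also covers sparse or
  edge-truncated windows.
- **Validation gates.** A window yields a valid vector only if its
  intensity s.d. is ≥ 1.0 (8-bit units; constant background has no
  signal) *and* its best correlation peak is ≥ 0.3. The peak gate is the
  package's own addition: windows containing only sensor noise pass the
  texture gate whenever the noise s.d. exceeds 1, but independent noise
  correlates weakly (max ZNCC ≈ 0.15 over a ±15 px search for 21×21
  windows), so 0.3 cleanly separates real pattern matches from noise.
- **Successive abandonment.** Up to 5 candidate peaks per window are
  ranked by correlation value. A candidate is abandoned when its
  distance from the median displacement of the (up to 8) neighboring
  windows exceeds `max(2 px, 3 × MAD)`, promoting the next-ranked peak;
  exhausting all candidates marks the vector invalid. With fewer than 3
  valid neighbors there is no meaningful consensus and the top peak is
  accepted. The exact historical rejection rule behind the method's name
  is not publicly specified; this ranked-candidate/neighborhood-median
  reconstruction is an interpretation built from its purpose, in the
  spirit of the normalized-median validation standard in PIV.
- **Timestamping.** A displacement over `[t, t+dt]` measures the mean
  velocity of that interval, which the exponential law attains near the
  interval centre, so vectors carry the midpoint time. (Assigning the
  left endpoint instead would bias the fitted amplitude by a factor
  `(1 - e^{-k dt})/(k dt)` ≈ 0.96 at `k = 22`, `dt = 1/300`, while
  leaving `k` untouched.)

## Synthetic generator

The generator emulates a lateral high-speed recording of an expelled
cloud and provides exact ground truth for every downstream stage:

- The *front particle* moves with the full law `Vh(t) = A e^{-kt} + c`;
  its position is the closed-form integral, exact to machine precision.
  Interior particles move with per-particle velocity scale factors drawn
  uniformly from [0.5, 1.0] (the front particle is forced to 1.0 and
  zero initial offset, so it stays the maximal-x particle), plus initial
  position jitter (x uniform in [-4, 0] cm, y normal with 2 cm s.d.).
  The uniform scale-factor distribution is a stand-in: interior
  particles are observed to lag the front, but no measured distribution
  exists.
- When a particle's decaying velocity component `s·A·e^{-kt}` drops
  below the momentum floor (default 15 cm/s; 0 disables), it switches to
  a diffusive random walk (Gaussian increments of s.d.
  `diffusion_sd·√dt`, default 5 cm/√s) plus a uniform convection drift.
  For the cough preset the convection drift is set equal to `c = 27`
  cm/s, so post-momentum-loss motion is continuous with the decay law.
- Large droplets (default aerodynamic diameter 400 µm, density 1 g/cm³)
  additionally fall at their Stokes settling velocity
  `v = ρ d² g / (18 µ_air)` throughout (≈ 484 cm/s; their particle
  Reynolds number exceeds 1, so the true fall speed would be lower —
  they exist to exercise the exclusion rule, and are inertial: no
  diffusion switch).
- Rendering: each particle is an isotropic Gaussian blob (σ uniform in
  [1.2, 2.5] px, peak intensity uniform in [80, 220]) evaluated at pixel
  centres, plus additive Gaussian sensor noise (default s.d. 2), clipped
  to [0, 255]. Default seeding is 200 fine particles, giving several
  particles per interrogation window over the cloud.
- Randomness: one `numpy` generator seeded from `seed` drives all
  trajectory/appearance draws in documented order; frame noise uses a
  child stream spawned from the same seed so rendering does not perturb
  the trajectories.

What the generator does **not** emulate: scattering/illumination optics,
out-of-plane (3-D) motion, particle size evolution (evaporation,
coagulation), turbulent swirls at the cloud periphery, and inhomogeneous
background lighting. Passing tests therefore demonstrate that the
analysis chain recovers kinematics from ideal-optics image sequences
with realistic geometry, noise and seeding — not that it is robust to
every artifact of a real recording.

## Analysis windows and problem sizes

The reference analyses use 120 frames (0.4 s at 300 frames/s) of
640×400 px, ≈ 200 particles, and fit over 0.04–0.20 s for the sneeze
(earlier frames are too dense for individual tracking) and 0.03–0.20 s
for the cough. The scaled-down pipeline tests use 0.1–0.2 s recordings
at 320–400 px width with the same particle density; these sizes recover
the decay rate within the tolerances stated in each test while keeping
the suite quick.

Non-positive extracted front velocities (possible at late frames where
true front motion is ~0.3 px/frame, below the tracking noise) are
dropped before fitting: the decay law is strictly positive and a
retreating front is a tracking artifact.

## Known limitations

- The front-line `h` is quantized to window centres (≈ 4.4 cm steps); the
  fit uses only `(t, Vh)`, so this affects reported positions, not rates.
- Window velocities are intensity-weighted mixtures of the particles in
  the window; with sparse seeding the front window can blend particles
  of different speeds. Dense seeding (several particles per window)
  keeps this bias within a few percent.
- The fitted model constrains `A, k > 0`, `c ≥ 0`; events that do not
  decay exponentially (e.g., multi-burst coughs) will fit poorly —
  inspect `rms`.
- Only single-axis (horizontal) kinematics are modelled; vertical motion
  is used solely for droplet exclusion.
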