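# Methods

## What the package models

`aqueflow` simulates and reconstructs a real-time, golden-angle radial,
velocity-encoded (phase-contrast) MRI acquisition of pulsatile flow in a
narrow channel, and quantifies how faithfully the reconstruction recovers
slow (respiratory-band) and fast (cardiac-band) flow oscillations. The
application it emulates is CSF flow measurement in the cerebral aqueduct, a
1–3 mm passage where respiratory-driven flow is of physiological interest
but the required combination of high spatial resolution (≈0.6 mm) and high
temporal resolution (≈168 ms) forces severe k-space undersampling.

The chain is:

1. **Numerical phantom** — a modified Shepp-Logan scene with a circular
   "aqueduct" disc whose through-plane velocity is
   `v(t) = A_r sin(2π f_r t + φ_r) + A_c sin(2π f_c t + φ_c)`.
   Velocity enters as phase via the phase-contrast relation: each of the two
   interleaved velocity encodings contributes `±(π/2)·v/VENC`, so the
   encoding phase difference is `π·v/VENC` (v = VENC maps to a phase
   difference of π, the standard VENC definition).
2. **Acquisition** — one radial spoke per TR; the encoding sign alternates
   every TR; the spoke angle advances by the golden angle
   (111.246° = 180°/φ) every second TR so both encodings of a pair share an
   angle. The velocity is re-evaluated each TR and frozen during a readout.
   Eight smooth synthetic coil sensitivities weight the scene; acquisition
   is noise-free.
3. **Reconstruction** — frame binning (8 spokes per encoding per frame →
   8 × 2 × TR per frame, 168 ms at TR 10.5 ms), then per encoding either
   density-compensated gridding, CG-SENSE (per-frame least squares by
   conjugate gradients), or compressed sensing with a temporal
   total-variation penalty,
   `min_x ‖F_r S x − d‖₂² + λ‖Tx‖₁`,
   solved jointly over frames with FISTA. Velocity maps follow from complex
   division of the two encodings.
4. **Analysis** — ROI flow curves (mL/s), FFT amplitude ratios Q_R / Q_C of
   the respiratory and cardiac components against the programmed waveform,
   zero-phase FIR low-pass filtering to isolate respiratory flow,
   cranial/caudal/net flow volumes, magnitude-squared coherence against a
   respiratory trace, and agreement statistics (ICC(2,1), Bland–Altman,
   Dice, one-way ANOVA, OLS).

## Default study conditions

| parameter | default | note |
|---|---|---|
| aqueduct diameter d | 2.5 mm | ≈ 4.2 pixels at 0.6 mm |
| respiratory component | 3.02 cm/s at 15 cycles/min | |
| cardiac component | 2.76 cm/s at 60 cycles/min | sweeps go to 120 bpm |
| TR | 10.5 ms | sweeps go down to 2 ms |
| VENC | 15 cm/s | peak v ≤ 5.78 cm/s, no aliasing |
| spokes per frame | 8 per encoding | frame duration 168 ms |
| duration | 20 s | 5 respiratory periods |
| coils | 8 | synthetic loop sensitivities |
| λ (CS) | 10⁻⁶ | on max-normalized data, T with unit frame spacing |
| iterations | 100 | CG and FISTA |

The respiratory/cardiac amplitudes are the component amplitudes measured in
the oscillating-flow pump validation of the protocol this package models;
peak velocity stays well below VENC so no phase unwrapping is needed.

**Grid size.** The protocol's in vivo geometry is a 400×400 matrix over a
240 mm FOV (0.6 mm pixels). The package's default numerical phantom uses a
128×128 matrix over 76.8 mm at the same 0.6 mm pixel size. This keeps the
two quantities that drive the Q ratios — the aqueduct's extent in pixels
and the per-frame angular undersampling — while keeping a 100-iteration
CS reconstruction of 119 frames × 8 coils × 2 encodings tractable on a
single CPU (minutes instead of hours). The absolute Q values do shift with
the grid size: at 64×64 the problem is less undersampled relative to its
pixel count and both reconstructions land near Q ≈ 0.9, while at the
128×128 default CG-SENSE and CS(λ=10⁻⁶) land near Q ≈ 0.7–0.8. Scene
support, coil geometry, and aqueduct/tissue contrast are package choices;
the phantom study they emulate did not fix them.

**Readout oversampling.** Spokes carry `2 × matrix_size` samples spanning
|k| ≤ 0.5 cycles/pixel (Δk = 1/(2N)). With only N samples the discrete
radial sampling makes the gridding PSF replicate at a radius of N pixels,
and for a head that spans 0.92·N pixels those replica rings land just
outside the object and contaminate the image; 2× readout oversampling
pushes them to 2N at no FFT cost. This is also standard scanner practice.

## Numerical choices

* **NUFFT** — Kaiser-Bessel gridding with 2× grid oversampling, kernel
  width 4 (reconstruction) or 6 (simulation/oracles), Beatty's β. Forward
  error vs a direct DFT is ~10⁻³ (width 4) and ~10⁻⁵ (width 6); the adjoint
  is the exact algebraic adjoint, so operator adjoint tests hold to 10⁻⁶.
  The normal operator A^H A uses Toeplitz embedding on a 2N grid (two FFTs
  per coil-frame, no interpolation), with the kernel spectrum pre-shifted
  so the hot path needs no fftshift.
* **Simulation accuracy** — the static background is synthesized once per
  spoke angle with the width-6 NUFFT; the aqueduct's time-varying
  contribution (a handful of pixels) is added per TR by an exact direct
  Fourier sum. The two encodings of a static scene are bit-identical.
* **Density compensation** — Ram-Lak |k| weights scaled by the polar area
  element, the center sample weighted by `Δk/(2·n_spokes)`, plus per-spoke
  angular Voronoi-gap weights because golden-angle spokes are not exactly
  uniform (three-distance theorem).
* **Echo-shift estimation** squares the spoke samples before the lag-one
  autocorrelation: squaring doubles the linear phase but cancels the π
  jumps that sign changes of a (real object's) spectrum would otherwise
  inject into the slope estimate. On a single spoke, an object
  center-of-mass offset is indistinguishable from a hardware echo shift;
  both corrections are intended for scanner data with gradient-delay and
  eddy-current errors and are **off by default** in the simulated pipeline
  (`ReconConfig.phase_corrections`), because on ideal noise-free data they
  misread the genuine flow-induced phase asymmetry of the iso-center
  aqueduct as a hardware error (removing ~80 % of the recovered velocity
  amplitude in our measurements).
* **CG-SENSE** — conjugate gradients on the normal equations, zero
  initialization, 100 iterations. The relative *data* residual, which CG
  decreases monotonically, is tracked through the objective recurrence at
  no extra cost; it plateaus near 2×10⁻² in single precision for
  8-spoke frames, so no early stop triggers at the default tolerance.
* **FISTA / temporal TV** — gradient step 1/(2L) with L from 20 power
  iterations (seeded, cached per operator); TV prox by fast gradient
  projection on the dual, vectorized over pixels and complex-aware
  (magnitude clipping), validated against Condat's exact 1D solver. The
  dual variable absorbs the threshold so conditioning is
  weight-independent; in the small-threshold regime the dual converges in a
  few steps and exits early at an accuracy of 10⁻⁴·threshold.
  `monitor=True` evaluates the exact objective each iteration and applies a
  monotone (MFISTA-style) fallback; it costs one extra operator pass and is
  off in production runs.
* **Walsh maps** — per-pixel dominant eigenvector of the box-filtered
  (8×8) coil covariance, RSS-normalized, phase-referenced to the first
  coil. Maps are only determined where the object has signal; inside the
  dark (zero-signal) Shepp-Logan ellipses they are arbitrary, which is
  harmless because the complex division cancels any static map phase.
* **Q-ratio spectral estimate** — single-sided FFT amplitude `2|X_k|/N` at
  the bin nearest the target frequency, with 3-point quadratic
  interpolation when the frequency falls between bins; no window or
  detrending. Real-time and reference curves share the sampling grid, so
  leakage largely cancels in the ratio. The reference is the programmed
  analytic waveform times the rendered aqueduct mask area, sampled at the
  frame timestamps — in simulation the ground truth is known exactly, so
  no gated reference scan is synthesized.
* **FIR low-pass** — Parks–McClellan equiripple, passband ≤ 0.5 Hz with
  0.1 dB ripple, stopband ≥ 0.75 Hz with 20 dB single-pass attenuation,
  minimal odd order found from the Bellanger estimate plus a fine-grid
  verification loop; applied forward-backward (zero phase, 40 dB total)
  with reflect padding of one filter length.
* **Precision** — solvers default to complex64 (complex128 available via
  `ReconConfig(precision="double")`); simulation and oracles use
  complex128.

## What the synthetic data do and do not show

The generator reproduces the geometry- and reconstruction-driven behavior
of the method: temporal blurring of fast oscillations by frame binning and
temporal regularization, spatial blurring of a small bright channel by
undersampled radial sampling, and their dependence on heart rate, TR,
diameter and λ. It does not model noise, relaxation (T1/T2) or flip-angle
signal weighting, off-resonance/B0 effects, gradient-delay or eddy-current
trajectory errors, in-plane motion, or a physical gated reference scan.
Passing tests therefore validate the algorithmic chain under ideal
conditions; they do not certify accuracy on scanner data, where the same
pipeline showed additional underestimation attributable to noise and
hardware imperfections.

## Problem sizes used in tests and acceptance runs

Unit tests run on 32–64 pixel grids with seconds-long simulations. The
acceptance computation runs the full default conditions (128×128, 20 s,
119 frames, 100 iterations, both encodings, CG-SENSE and CS λ=10⁻⁶),
about 10 minutes on one CPU. Trend checks (heart rate, TR, diameter, λ)
run at 64×64 with 8.5 s acquisitions — two full respiratory periods, the
minimum for the respiratory spectral estimate — where each endpoint takes
under a minute.

## Known limitations

* Absolute Q values depend on the phantom grid size and scene choices (see
  above); trend directions are robust in our measurements, but the margins
  of the λ ordering are small at reduced scale.
* The λ scale is defined on max-normalized data with unit-spacing temporal
  differences; other toolboxes normalize differently, so λ values are
  comparable only in order of magnitude.
* ROI delineation for simulated data uses the ground-truth aqueduct mask;
  manual-mask import exists for real data but interobserver workflows are
  out of scope.
* Velocity anti-aliasing is not implemented (|v| ≤ VENC by construction in
  the simulation).
* The one-way ANOVA treats groups as independent; a repeated-measures
  variant is left as future work.
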