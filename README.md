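# aqueflow

Simulation, reconstruction and analysis of **real-time golden-angle radial
phase-contrast MRI** of cerebrospinal-fluid (CSF) flow in small passageways
such as the cerebral aqueduct.

CSF moves through the 1–3 mm cerebral aqueduct with both cardiac-driven
pulsation (~1 Hz) and slower respiratory-driven oscillation (~0.25 Hz).
Capturing the respiratory component requires *real-time* (ungated) imaging
at high spatial resolution, which forces severe k-space undersampling:
with 8 radial spokes per velocity encoding and TR = 10.5 ms, each velocity
map integrates 168 ms of data. `aqueflow` implements the full measurement
chain as testable code so the accuracy of such a protocol can be studied
numerically:

* a **numerical flow phantom** — a modified Shepp-Logan scene with a small
  circular "aqueduct" whose through-plane velocity
  `v(t) = A_r sin(2π f_r t) + A_c sin(2π f_c t)` enters the signal phase via
  the phase-contrast relation (encoding phase difference `π·v/VENC`),
  acquired spoke by spoke with golden-angle ordering (111.246° increments),
  alternating velocity encodings and 8 simulated receive coils, noise-free;
* **reconstruction** — density-compensated gridding, per-frame **CG-SENSE**,
  and **compressed sensing** with a temporal total-variation penalty

  $$\min_x \lVert F_r S x - d\rVert_2^2 + \lambda \lVert T x\rVert_1,$$

  where `F_r` is the radial NUFFT, `S` the (Walsh-estimated) coil
  sensitivities, `T` the first-order temporal difference and `λ` the
  regularization weight (default 10⁻⁶ on max-normalized data, 100
  iterations), followed by complex-division velocity mapping;
* **flow analysis** — ROI flow curves, the spectral accuracy indices
  **Q_R** and **Q_C** (FFT amplitude of the respiratory / cardiac component
  in the reconstructed flow divided by that of the programmed waveform;
  1 = accurate, < 1 = underestimation), zero-phase FIR isolation of
  respiratory flow, cranial/caudal/net flow volumes, and magnitude-squared
  coherence against a respiratory trace;
* **agreement statistics** — ICC(2,1) with the conventional qualitative
  labels, Bland–Altman, Dice, one-way ANOVA and OLS regression.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

Simulate a reduced-scale phantom (64×64 grid at the protocol's 0.6 mm
pixels, 8.5 s — two respiratory periods) and reconstruct with compressed
sensing:

```python
from aqueflow import (AcquisitionConfig, FlowWaveform, PhantomConfig,
                      ReconConfig, flow_volumes)
from aqueflow.experiments import run_pipeline

result = run_pipeline(
    phantom=PhantomConfig(matrix_size=64, fov_mm=38.4),
    waveform=FlowWaveform(),        # 3.02 cm/s @ 15/min + 2.76 cm/s @ 60 bpm
    acquisition=AcquisitionConfig(duration_s=8.5),
    recon_cfg=ReconConfig(mode="cs", lam=1e-6),
)
print(f"Q_R = {result.ratios.q_r:.3f}  (respiratory amplitude ratio)")
print(f"Q_C = {result.ratios.q_c:.3f}  (cardiac amplitude ratio)")
vols = flow_volumes(result.rt_curve)
print(f"cranial {vols.cranial_ml_min:+.2f}  caudal {vols.caudal_ml_min:+.2f}  "
      f"net {vols.net_ml_min:+.2f}  mL/min")
```

prints

```
Q_R = 0.933  (respiratory amplitude ratio)
Q_C = 0.896  (cardiac amplitude ratio)
cranial +3.28  caudal -2.87  net +0.41  mL/min
```

Both ratios sit below 1 — the reconstruction underestimates the programmed
oscillations — and the cardiac ratio is lower than the respiratory one: the
temporal regularization and 168 ms frames damp fast oscillations more than
slow ones. At the full default scale (128×128, 20 s) the undersampling is
more severe and both reconstructions land near Q ≈ 0.7–0.8. The `net` value
is the residual of two nearly equal cranial/caudal volumes, which is why net
flow is the noisiest of the three in practice.

A command-line interface mirrors the library:

```bash
aqueflow simulate --config config.yaml --out raw.h5
aqueflow recon --in raw.h5 --mode cs --lambda 1e-6 --iters 100 --out rec
aqueflow analyze --vel rec.h5 --roi roi.npy --out analysis/
aqueflow sweep --parameter diameter --values 2,4,6,8,10 --out sweep/
aqueflow stats --in measurements.csv --out report.csv
aqueflow fixtures --size tiny --out fixtures/
```

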