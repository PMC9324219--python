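"""End-to-end numerical experiments: baseline Q-ratio analysis and sweeps.

Drives the full chain: phantom simulation -> reconstruction -> ROI flow ->
spectral Q-ratios against the programmed analytic waveform.  The analytic
waveform sampled at the frame timestamps serves as the reference (in the
simulation the ground truth is known exactly, so no gated reference scan is
synthesized).

Four one-parameter sweeps mirror the numerical study design: heart rate
(60-120 bpm in steps of 15), TR (2-10.5 ms), aqueduct diameter (2-10 mm)
and the regularization weight lambda (1e-9 to 1e-2, half-decade steps),
all around the baseline d = 2.5 mm, 60 bpm, TR = 10.5 ms, 8 spokes/frame.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .flow import FlowCurve, SpectralRatios, flow_volumes, q_ratios, roi_flow
from .phantom import (
    AcquisitionConfig,
    FlowWaveform,
    PhantomConfig,
    RadialKSpace,
    Scene,
    build_scene,
    evaluate_velocity,
    simulate_coil_maps,
    simulate_kspace,
)
from .recon import ReconConfig, prepare_recon, reconstruct, run_prepared

log = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "PipelineResult",
    "simulate_phantom",
    "reference_flow_curve",
    "run_pipeline",
    "run_sweep",
    "run_phantom_analysis",
    "make_fixtures",
    "write_provenance",
]

#: half-decade lambda grid of the regularization sweep
LAMBDA_GRID = [10.0 ** e for e in np.arange(-9.0, -1.5, 0.5)]


@dataclass
class SweepSpec:
    """One-parameter sweep around the immutable baseline.

    ``parameter`` is one of ``heart_rate`` (bpm), ``tr`` (ms), ``diameter``
    (mm) or ``lambda``; ``values`` the settings to simulate.
    """

    parameter: str
    values: list

    def __post_init__(self) -> None:
        if self.parameter not in ("heart_rate", "tr", "diameter", "lambda"):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if not self.values:
            raise ValueError("sweep needs at least one value")


@dataclass
class PipelineResult:
    ratios: SpectralRatios
    rt_curve: FlowCurve
    ref_curve: FlowCurve
    scene: Scene


def simulate_phantom(
    phantom: PhantomConfig | None = None,
    waveform: FlowWaveform | None = None,
    acquisition: AcquisitionConfig | None = None,
) -> tuple[RadialKSpace, Scene]:
    """Simulate baseline (or overridden) phantom raw data; returns (raw, scene)."""
    phantom = phantom or PhantomConfig()
    waveform = waveform or FlowWaveform()
    acquisition = acquisition or AcquisitionConfig()
    scene = build_scene(phantom)
    maps = simulate_coil_maps(phantom.n_coils, phantom.matrix_size)
    raw = simulate_kspace(scene, waveform, maps, acquisition)
    return raw, scene


def reference_flow_curve(
    waveform: FlowWaveform, scene: Scene, times_s: np.ndarray
) -> FlowCurve:
    """Analytic ground-truth flow over the rendered aqueduct mask (mL/s)."""
    area_mm2 = scene.aqueduct_mask.sum() * scene.pixel_mm**2
    v = evaluate_velocity(waveform, times_s)
    dt = float(np.mean(np.diff(times_s))) if times_s.size > 1 else 1.0
    return FlowCurve(v * area_mm2 * 1e-2, dt, v)


def run_pipeline(
    phantom: PhantomConfig | None = None,
    waveform: FlowWaveform | None = None,
    acquisition: AcquisitionConfig | None = None,
    recon_cfg: ReconConfig | None = None,
) -> PipelineResult:
    """Simulate, reconstruct and compute Q_R / Q_C for one configuration."""
    phantom = phantom or PhantomConfig()
    waveform = waveform or FlowWaveform()
    acquisition = acquisition or AcquisitionConfig()
    recon_cfg = recon_cfg or ReconConfig()
    raw, scene = simulate_phantom(phantom, waveform, acquisition)
    vel, _, _ = reconstruct(raw, recon_cfg)
    rt = roi_flow(vel, scene.aqueduct_mask)
    ref = reference_flow_curve(waveform, scene, vel.times_s)
    ratios = q_ratios(
        rt,
        ref,
        waveform.resp_frequency_cpm / 60.0,
        waveform.card_frequency_cpm / 60.0,
    )
    return PipelineResult(ratios, rt, ref, scene)


def _apply_sweep_value(parameter: str, value, phantom, waveform, acquisition, recon):
    phantom = dataclasses.replace(phantom)
    waveform = dataclasses.replace(waveform)
    acquisition = dataclasses.replace(acquisition)
    recon = dataclasses.replace(recon)
    if parameter == "heart_rate":
        waveform.card_frequency_cpm = float(value)
    elif parameter == "tr":
        acquisition.tr_ms = float(value)
    elif parameter == "diameter":
        phantom.aqueduct_diameter_mm = float(value)
    elif parameter == "lambda":
        recon.lam = float(value)
        recon.mode = "cs"
    return phantom, waveform, acquisition, recon


def run_sweep(
    spec: SweepSpec,
    recon_cfg: ReconConfig | None = None,
    phantom: PhantomConfig | None = None,
    waveform: FlowWaveform | None = None,
    acquisition: AcquisitionConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run one parameter sweep; returns a (value, q_r, q_c) table.

    A failing stage aborts that value with a logged diagnostic, not the
    sweep (the row is recorded with NaN ratios).  When ``out_dir`` is given,
    the table (CSV) and a provenance file are written there.
    """
    recon_cfg = recon_cfg or ReconConfig()
    phantom = phantom or PhantomConfig()
    waveform = waveform or FlowWaveform()
    acquisition = acquisition or AcquisitionConfig()
    rows = []
    for value in spec.values:
        ph, wf, acq, rc = _apply_sweep_value(
            spec.parameter, value, phantom, waveform, acquisition, recon_cfg
        )
        try:
            res = run_pipeline(ph, wf, acq, rc)
            rows.append(
                {"value": value, "q_r": res.ratios.q_r, "q_c": res.ratios.q_c}
            )
        except Exception:
            log.exception("sweep value %r failed", value)
            rows.append({"value": value, "q_r": np.nan, "q_c": np.nan})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"sweep_{spec.parameter}.csv", index=False)
        write_provenance(
            out_dir / "provenance.json",
            sweep=dataclasses.asdict(spec),
            phantom=dataclasses.asdict(phantom),
            waveform=dataclasses.asdict(waveform),
            acquisition=dataclasses.asdict(acquisition),
            recon=dataclasses.asdict(recon_cfg),
        )
    return table


def run_phantom_analysis(
    recon_variants: list[ReconConfig] | None = None,
    phantom: PhantomConfig | None = None,
    waveform: FlowWaveform | None = None,
    acquisition: AcquisitionConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Baseline phantom analysis across reconstruction variants.

    Simulates once, reconstructs with each requested mode/lambda, extracts
    the ROI flow curve and reports Q_R, Q_C and flow volumes per variant.
    """
    recon_variants = recon_variants or [
        ReconConfig(mode="cgsense"),
        ReconConfig(mode="cs", lam=1e-6),
    ]
    phantom = phantom or PhantomConfig()
    waveform = waveform or FlowWaveform()
    acquisition = acquisition or AcquisitionConfig()
    raw, scene = simulate_phantom(phantom, waveform, acquisition)
    prep = prepare_recon(raw, recon_variants[0])
    rows = []
    for rc in recon_variants:
        vel, _, _ = run_prepared(prep, rc)
        rt = roi_flow(vel, scene.aqueduct_mask)
        ref = reference_flow_curve(waveform, scene, vel.times_s)
        ratios = q_ratios(
            rt,
            ref,
            waveform.resp_frequency_cpm / 60.0,
            waveform.card_frequency_cpm / 60.0,
        )
        vols = flow_volumes(rt)
        rows.append(
            {
                "mode": rc.mode,
                "lambda": rc.lam if rc.mode == "cs" else 0.0,
                "q_r": ratios.q_r,
                "q_c": ratios.q_c,
                "cranial_ml_min": vols.cranial_ml_min,
                "caudal_ml_min": vols.caudal_ml_min,
                "net_ml_min": vols.net_ml_min,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "phantom_analysis.csv", index=False)
        write_provenance(
            out_dir / "provenance.json",
            phantom=dataclasses.asdict(phantom),
            waveform=dataclasses.asdict(waveform),
            acquisition=dataclasses.asdict(acquisition),
            recon_variants=[dataclasses.asdict(r) for r in recon_variants],
        )
    return table


FIXTURE_SIZES = {
    "tiny": dict(matrix_size=96, fov_mm=57.6, duration_s=6.0),
    "baseline": dict(matrix_size=128, fov_mm=76.8, duration_s=20.0),
}


def make_fixtures(size: str, out_dir: str | Path) -> dict:
    """Write a deterministic simulated raw-data fixture and its checksum.

    ``tiny`` uses a 96 x 96 grid and 6 s duration; ``baseline`` the default
    geometry and 20 s.  The checksum covers the raw arrays, so regeneration
    is bit-reproducible.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    p = FIXTURE_SIZES[size]
    phantom = PhantomConfig(matrix_size=p["matrix_size"], fov_mm=p["fov_mm"])
    acq = AcquisitionConfig(duration_s=p["duration_s"])
    raw, _ = simulate_phantom(phantom, FlowWaveform(), acq)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5_path = out_dir / f"{size}.h5"
    raw.save(str(h5_path))
    digest = hashlib.sha256()
    for arr in (raw.data, raw.angles_deg, raw.times_s, raw.enc_sign):
        digest.update(np.ascontiguousarray(arr).tobytes())
    checksum = digest.hexdigest()
    meta = {"size": size, "sha256": checksum, "file": h5_path.name}
    (out_dir / f"{size}.sha256.json").write_text(json.dumps(meta, indent=2))
    return meta


def write_provenance(path: str | Path, **sections) -> None:
    """Machine-readable record of every configuration used in a run."""
    payload = {"aqueflow_version": __version__, **sections}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
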