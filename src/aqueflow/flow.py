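"""Flow-curve extraction and validation measures for velocity-map time series.

Turns reconstructed velocity maps into volumetric flow curves (mL/s) in an
ROI and computes the summary measures used to validate real-time CSF flow
imaging: FFT amplitude ratios of the respiratory and cardiac oscillation
components against a reference (Q_R, Q_C), respiratory-only flow via a
zero-phase FIR low-pass, cranial/caudal/net flow volumes, magnitude-squared
coherence with a respiratory bellows trace, background phase correction,
and rigid ROI tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .recon import VelocitySeries

__all__ = [
    "FlowCurve",
    "SpectralRatios",
    "FlowVolumes",
    "background_phase_correct",
    "roi_flow",
    "track_roi",
    "component_amplitude",
    "q_ratios",
    "design_lowpass",
    "lowpass_zero_phase",
    "flow_volumes",
    "coherence_at_resp",
]


@dataclass
class FlowCurve:
    """Uniformly sampled volumetric flow: samples in mL/s, dt in seconds."""

    samples: np.ndarray
    dt_s: float
    mean_velocity_cm_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("flow curve contains non-finite values")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_s

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "flow_ml_s": self.samples})


@dataclass
class SpectralRatios:
    """Amplitude ratios real-time/reference for the two oscillation components.

    ``q_r`` (respiratory) and ``q_c`` (cardiac) equal 1 for perfectly
    accurate real-time quantification; < 1 indicates underestimation.
    """

    q_r: float
    q_c: float
    r_rt: float
    r_ref: float
    c_rt: float
    c_ref: float


@dataclass
class FlowVolumes:
    """Cranial (+), caudal (-, signed) and net flow in mL/min."""

    cranial_ml_min: float
    caudal_ml_min: float
    net_ml_min: float


def background_phase_correct(
    vmap: VelocitySeries, static_mask: np.ndarray
) -> VelocitySeries:
    """Subtract a first-order polynomial (plane) fitted to static tissue.

    Per frame, ``a + b*x + c*y`` is least-squares fitted to the velocities on
    ``static_mask`` and subtracted from the whole map.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.sum() < 3:
        raise ValueError("need at least 3 static pixels for a plane fit")
    ny, nx = vmap.velocity.shape[-2:]
    Y, X = np.mgrid[0:ny, 0:nx].astype(float)
    design = np.column_stack(
        [np.ones(static_mask.sum()), X[static_mask], Y[static_mask]]
    )
    full = np.column_stack([np.ones(ny * nx), X.ravel(), Y.ravel()])
    out = vmap.velocity.copy()
    for f in range(out.shape[0]):
        coef, *_ = np.linalg.lstsq(design, out[f][static_mask], rcond=None)
        out[f] -= (full @ coef).reshape(ny, nx)
    return VelocitySeries(
        out, vmap.magnitude, vmap.venc_cm_s, vmap.times_s, vmap.pixel_mm
    )


def roi_flow(
    vmap: VelocitySeries,
    roi_mask: np.ndarray | list[np.ndarray],
    pixel_area_mm2: float | None = None,
) -> FlowCurve:
    """Volumetric flow in the ROI: sum of velocity x pixel area per frame.

    Velocities (cm/s) times area (mm^2) are converted to mL/s via the factor
    1e-2.  ``roi_mask`` may be a single mask or one mask per frame (from
    :func:`track_roi`).  The ROI mean velocity is attached to the curve.
    """
    if pixel_area_mm2 is None:
        pixel_area_mm2 = vmap.pixel_mm**2
    n_frames = vmap.velocity.shape[0]
    masks = (
        roi_mask
        if isinstance(roi_mask, list)
        else [np.asarray(roi_mask, dtype=bool)] * n_frames
    )
    if not any(m.any() for m in masks):
        raise ValueError("empty ROI")
    flow = np.array(
        [vmap.velocity[f][masks[f]].sum() * pixel_area_mm2 * 1e-2 for f in range(n_frames)]
    )
    mean_v = np.array([vmap.velocity[f][masks[f]].mean() for f in range(n_frames)])
    dt = float(np.mean(np.diff(vmap.times_s))) if n_frames > 1 else 1.0
    return FlowCurve(flow, dt, mean_v)


def track_roi(
    magnitude: np.ndarray,
    initial_mask: np.ndarray,
    search_radius: int = 5,
    pad: int = 4,
) -> list[np.ndarray]:
    """Track the ROI through the series by rigid integer-pixel translation.

    Per frame, the shift maximizing the normalized cross-correlation of a
    patch around the ROI against frame 0 is found over a square search
    window; the mask is shifted accordingly.  A correlation peak on the
    window edge triggers a warning (tracking may have lost the target).
    """
    import logging

    log = logging.getLogger(__name__)
    initial_mask = np.asarray(initial_mask, dtype=bool)
    ys, xs = np.nonzero(initial_mask)
    if ys.size == 0:
        raise ValueError("empty initial mask")
    ny, nx = magnitude.shape[-2:]
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, ny)
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, nx)
    ref = magnitude[0, y0:y1, x0:x1]
    ref_z = (ref - ref.mean()) / (ref.std() + 1e-12)

    masks = [initial_mask]
    for f in range(1, magnitude.shape[0]):
        best, best_shift = -np.inf, (0, 0)
        for dy in range(-search_radius, search_radius + 1):
            for dx in range(-search_radius, search_radius + 1):
                yy0, yy1 = y0 + dy, y1 + dy
                xx0, xx1 = x0 + dx, x1 + dx
                if yy0 < 0 or xx0 < 0 or yy1 > ny or xx1 > nx:
                    continue
                patch = magnitude[f, yy0:yy1, xx0:xx1]
                pz = (patch - patch.mean()) / (patch.std() + 1e-12)
                score = float((ref_z * pz).mean())
                if score > best:
                    best, best_shift = score, (dy, dx)
        dy, dx = best_shift
        if search_radius > 0 and (abs(dy) == search_radius or abs(dx) == search_radius):
            log.warning("tracking correlation peak at search-window edge (frame %d)", f)
        masks.append(np.roll(np.roll(initial_mask, dy, axis=0), dx, axis=1))
    return masks


def component_amplitude(curve: FlowCurve, f_hz: float) -> float:
    """Single-sided FFT amplitude of the oscillation component at ``f_hz``.

    Returns ``2 |X_k| / N`` at the discrete bin nearest ``f_hz`` (DC
    excluded).  When the target frequency falls between bins, the amplitude
    is read off a quadratic fit of |FFT| through the three bins around the
    maximum-magnitude neighbor, which compensates most of the scalloping
    loss.  No window or detrending is applied.
    """
    n = curve.samples.size
    fs = 1.0 / curve.dt_s
    if f_hz >= fs / 2:
        raise ValueError("component frequency at or above Nyquist")
    if curve.duration_s < 2.0 / f_hz:
        raise ValueError("curve must cover at least two periods of the component")
    spec = np.abs(np.fft.rfft(curve.samples)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, curve.dt_s)
    k = int(np.argmin(np.abs(freqs - f_hz)))
    k = max(k, 1)  # exclude DC
    df = freqs[1]
    if abs(freqs[k] - f_hz) < 1e-9 * df or k < 1 or k + 1 >= spec.size:
        return float(spec[k])
    # quadratic interpolation of |FFT| over the 3 bins around k
    y = spec[k - 1 : k + 2]
    x = freqs[k - 1 : k + 2]
    coef = np.polyfit(x - freqs[k], y, 2)
    return float(np.polyval(coef, f_hz - freqs[k]))


def q_ratios(
    rt: FlowCurve, ref: FlowCurve, f_resp_hz: float, f_card_hz: float
) -> SpectralRatios:
    """Respiratory and cardiac amplitude ratios Q_R, Q_C (real-time/reference)."""
    r_rt = component_amplitude(rt, f_resp_hz)
    r_ref = component_amplitude(ref, f_resp_hz)
    c_rt = component_amplitude(rt, f_card_hz)
    c_ref = component_amplitude(ref, f_card_hz)
    if r_ref == 0 or c_ref == 0:
        raise ValueError("reference component amplitude is zero")
    return SpectralRatios(r_rt / r_ref, c_rt / c_ref, r_rt, r_ref, c_rt, c_ref)


def design_lowpass(
    fs_hz: float,
    passband_hz: float = 0.5,
    stopband_hz: float = 0.75,
    ripple_db: float = 0.1,
    atten_db: float = 20.0,
) -> np.ndarray:
    """Minimum-order equiripple FIR low-pass meeting the band specifications.

    Passband up to ``passband_hz`` with at most ``ripple_db`` peak-to-peak
    ripple; stopband from ``stopband_hz`` with at least ``atten_db``
    single-pass attenuation.  The order starts at the Bellanger estimate and
    grows until a fine frequency-grid check passes.
    """
    if fs_hz <= 2 * stopband_hz:
        raise ValueError("sampling rate too low for the requested stopband")
    rp = 10 ** (ripple_db / 20.0)
    delta_p = (rp - 1) / (rp + 1)
    delta_s = 10 ** (-atten_db / 20.0)
    dfn = (stopband_hz - passband_hz) / fs_hz
    est = int(np.ceil((-20 * np.log10(np.sqrt(delta_p * delta_s)) - 13) / (14.6 * dfn)))
    for numtaps in range(max(est, 5), est + 80):
        if numtaps % 2 == 0:
            continue  # odd length: symmetric type-I filter
        taps = signal.remez(
            numtaps,
            [0, passband_hz, stopband_hz, fs_hz / 2],
            [1, 0],
            weight=[1 / delta_p, 1 / delta_s],
            fs=fs_hz,
        )
        w, h = signal.freqz(taps, worN=4096, fs=fs_hz)
        pb = np.abs(h[w <= passband_hz])
        sb = np.abs(h[w >= stopband_hz])
        if pb.min() >= 1 - delta_p * 1.01 and pb.max() <= 1 + delta_p * 1.01 and sb.max() <= delta_s * 1.01:
            return taps
    raise RuntimeError("FIR design failed to meet specifications")


def lowpass_zero_phase(
    curve: FlowCurve,
    passband_hz: float = 0.5,
    stopband_hz: float = 0.75,
    ripple_db: float = 0.1,
    atten_db: float = 20.0,
) -> FlowCurve:
    """Zero-phase low-pass: the FIR filter applied forward then backward.

    The forward-backward application doubles the stopband attenuation
    (2 x 20 dB = 40 dB) and cancels the filter delay.  The series is
    reflect-padded by one filter length at each end.
    """
    fs = 1.0 / curve.dt_s
    taps = design_lowpass(fs, passband_hz, stopband_hz, ripple_db, atten_db)
    if curve.samples.size < 3 * taps.size:
        raise ValueError(
            f"curve ({curve.samples.size} samples) shorter than 3x filter "
            f"length ({taps.size})"
        )
    filtered = signal.filtfilt(taps, [1.0], curve.samples, padlen=taps.size)
    return FlowCurve(filtered, curve.dt_s)


def flow_volumes(curve: FlowCurve) -> FlowVolumes:
    """Cranial/caudal/net flow volumes per unit time (mL/min).

    Positive frames integrate to the cranial volume, negative frames to the
    caudal volume (reported signed); each sum is divided by the scan
    duration and scaled to minutes.  ``net = cranial + caudal`` exactly.
    """
    if curve.samples.size == 0:
        raise ValueError("empty flow curve")
    dur = curve.duration_s
    cranial = float(np.sum(np.maximum(curve.samples, 0.0)) * curve.dt_s / dur * 60.0)
    caudal = float(np.sum(np.minimum(curve.samples, 0.0)) * curve.dt_s / dur * 60.0)
    return FlowVolumes(cranial, caudal, cranial + caudal)


def coherence_at_resp(
    flow: FlowCurve, bellows: np.ndarray, fs_hz: float | None = None
) -> tuple[float, float]:
    """Magnitude-squared coherence between flow and the bellows trace.

    Welch-averaged over eight segments with 50% overlap.  The respiratory
    frequency is the peak of the bellows power spectral density (DC
    excluded); returns ``(f_resp_hz, coherence at f_resp)``.
    """
    bellows = np.asarray(bellows, dtype=float)
    if bellows.size != flow.samples.size:
        raise ValueError("flow and bellows series must have equal length")
    fs = fs_hz or 1.0 / flow.dt_s
    nperseg = int(2 * flow.samples.size / 9)  # 8 segments at 50% overlap
    if nperseg < 8:
        raise ValueError("series too short for eight Welch segments")
    noverlap = nperseg // 2
    f_psd, psd = signal.welch(bellows, fs=fs, nperseg=nperseg, noverlap=noverlap)
    f_resp = float(f_psd[1:][np.argmax(psd[1:])])
    f_coh, coh = signal.coherence(
        flow.samples, bellows, fs=fs, nperseg=nperseg, noverlap=noverlap
    )
    c = float(coh[np.argmin(np.abs(f_coh - f_resp))])
    return f_resp, min(max(c, 0.0), 1.0)


def load_bellows_csv(path: str, dt_s: float, n_samples: int) -> np.ndarray:
    """Read a two-column (time_s, amplitude) CSV and resample to the flow rate."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    a = df.iloc[:, 1].to_numpy(dtype=float)
    target = np.arange(n_samples) * dt_s
    return np.interp(target, t, a)
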