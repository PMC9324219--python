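"""Numerical flow phantom: scene, flow waveform, coil maps and radial k-space.

The simulated scene is a modified Shepp-Logan head phantom with a small
circular "aqueduct" whose through-plane velocity is the superposition of a
slow respiratory sinusoid and a faster cardiac sinusoid.  Velocity enters the
signal as a phase via the phase-contrast relation (``+/- pi/2 * v / VENC``
per velocity encoding, so the encoding difference spans pi at v = VENC).
Acquisition proceeds spoke by spoke: at every TR the simulation time advances,
the velocity is re-evaluated, the encoding sign alternates, and the spoke
angle advances by the golden angle every second TR (the two encodings of a
pair share an angle).  Eight smooth synthetic coil sensitivities multiply the
scene; no noise is added.

The background (everything outside the aqueduct) is static, so its radial
samples are synthesized once per unique spoke angle with a high-accuracy
NUFFT; the aqueduct contribution (a handful of pixels) is added per TR by an
exact direct Fourier sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .nufft import NufftPlan
from .trajectory import golden_angles, spoke_coords

__all__ = [
    "PhantomConfig",
    "FlowWaveform",
    "AcquisitionConfig",
    "Scene",
    "RadialKSpace",
    "build_scene",
    "evaluate_velocity",
    "velocity_to_phase",
    "simulate_coil_maps",
    "simulate_kspace",
]

# Modified Shepp-Logan ellipses: (intensity, a, b, x0, y0, phi_deg) in the
# conventional [-1, 1]^2 frame, intensities additive.
_SHEPP_LOGAN = np.array(
    [
        [1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0],
        [-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0],
        [-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0],
        [-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0],
        [0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0],
        [0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0],
        [0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0],
        [0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0],
    ]
)


@dataclass
class PhantomConfig:
    """Geometry and signal magnitudes of the numerical phantom.

    The default grid is 128 x 128 at the protocol's 0.6 mm pixel size
    (FOV 76.8 mm), which keeps the aqueduct's extent in pixels identical to
    the full 400 x 400 / 240 mm in vivo geometry while staying tractable for
    iterative reconstruction on a single CPU.
    """

    matrix_size: int = 128
    fov_mm: float = 76.8
    aqueduct_center_mm: tuple[float, float] = (0.0, 0.0)
    aqueduct_diameter_mm: float = 2.5
    aqueduct_magnitude: float = 1.0
    tissue_magnitude: float = 0.2
    n_coils: int = 8

    def __post_init__(self) -> None:
        if self.matrix_size % 2:
            raise ValueError("matrix_size must be even")
        if self.aqueduct_diameter_mm <= 0:
            raise ValueError("aqueduct_diameter_mm must be > 0")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix_size


@dataclass
class FlowWaveform:
    """Two-component sinusoidal through-plane velocity waveform (cm/s).

    Default amplitudes follow the oscillating-flow validation setup: a
    respiratory component of 3.02 cm/s at 15 cycles/min and a cardiac
    component of 2.76 cm/s at 60 cycles/min.
    """

    resp_amplitude: float = 3.02
    resp_frequency_cpm: float = 15.0
    card_amplitude: float = 2.76
    card_frequency_cpm: float = 60.0
    resp_phase: float = 0.0
    card_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.resp_frequency_cpm <= 0 or self.card_frequency_cpm <= 0:
            raise ValueError("frequencies must be > 0")
        if self.resp_frequency_cpm >= self.card_frequency_cpm:
            raise ValueError("respiratory frequency must be below cardiac")


@dataclass
class AcquisitionConfig:
    """Radial velocity-encoded acquisition parameters.

    ``flip_angle_deg``, ``te_ms`` and ``bandwidth_hz`` are carried as
    metadata only; relaxation and excitation are not simulated.
    """

    tr_ms: float = 10.5
    venc_cm_s: float = 15.0
    spokes_per_frame: int = 8
    n_encodings: int = 2
    duration_s: float = 20.0
    #: samples per spoke; None selects twice the matrix size (2x readout
    #: oversampling, so the radial sampling FOV is twice the image and the
    #: discrete-sampling PSF replicas stay clear of the object)
    readout_samples: int | None = None
    flip_angle_deg: float = 7.0
    te_ms: float = 5.1
    bandwidth_hz: float = 208.0

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        if self.venc_cm_s <= 0:
            raise ValueError("venc_cm_s must be > 0")
        if self.spokes_per_frame < 1:
            raise ValueError("spokes_per_frame must be >= 1")
        if self.n_encodings != 2:
            raise ValueError("only two interleaved velocity encodings are supported")


@dataclass
class Scene:
    """Rendered phantom: complex image, aqueduct pixel mask, pixel size."""

    image: np.ndarray
    aqueduct_mask: np.ndarray
    pixel_mm: float


@dataclass
class RadialKSpace:
    """Raw radial velocity-encoded k-space data in chronological spoke order.

    ``data`` has shape (n_spokes, n_samples, n_coils); ``angles_deg``,
    ``times_s`` and ``enc_sign`` (+1/-1) are per spoke.  ``attrs`` carries the
    generating configuration for provenance.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    times_s: np.ndarray
    enc_sign: np.ndarray
    attrs: dict = field(default_factory=dict)

    @property
    def n_spokes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    def encoding(self, sign: int) -> "RadialKSpace":
        """Sub-set of spokes with the given encoding sign (chronological)."""
        sel = self.enc_sign == sign
        return RadialKSpace(
            self.data[sel],
            self.angles_deg[sel],
            self.times_s[sel],
            self.enc_sign[sel],
            dict(self.attrs),
        )

    def spokes_to_csv(self, path: str) -> None:
        """Debug dump: ``spoke_index,angle_deg,time_s,enc_sign`` per spoke."""
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["spoke_index", "angle_deg", "time_s", "enc_sign"])
            for i in range(self.n_spokes):
                w.writerow(
                    [i, self.angles_deg[i], self.times_s[i], int(self.enc_sign[i])]
                )

    def save(self, path: str) -> None:
        """Write to HDF5: /data, /angles, /times, /enc_sign + config attrs."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("angles", data=self.angles_deg)
            f.create_dataset("times", data=self.times_s)
            f.create_dataset("enc_sign", data=self.enc_sign)
            for k, v in self.attrs.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path: str) -> "RadialKSpace":
        with h5py.File(path, "r") as f:
            return cls(
                f["data"][()],
                f["angles"][()],
                f["times"][()],
                f["enc_sign"][()],
                dict(f.attrs),
            )


def _normalized_grid(n: int, fov_mm: float, pixel_mm: float):
    """Pixel-center coordinates in the conventional [-1, 1] phantom frame."""
    half_fov = fov_mm / 2.0
    coords_mm = (np.arange(n) - n // 2) * pixel_mm
    x = coords_mm / half_fov
    y = coords_mm / half_fov
    return np.meshgrid(x, y)  # (X, Y) indexed [row=y, col=x]


def _shepp_logan(n: int, fov_mm: float, pixel_mm: float) -> np.ndarray:
    X, Y = _normalized_grid(n, fov_mm, pixel_mm)
    img = np.zeros((n, n))
    for inten, a, b, x0, y0, phi in _SHEPP_LOGAN:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (X - x0) * c + (Y - y0) * s
        yr = -(X - x0) * s + (Y - y0) * c
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += inten
    return img


def build_scene(cfg: PhantomConfig) -> Scene:
    """Render the modified Shepp-Logan scene with an aqueduct disc.

    The Shepp-Logan intensities are rescaled so that the tissue underlying
    the aqueduct equals ``tissue_magnitude``; pixels whose centers fall within
    the aqueduct disc are overwritten with ``aqueduct_magnitude``.  The phase
    is zero everywhere (velocity phase is applied at acquisition time).
    """
    n = cfg.matrix_size
    pix = cfg.pixel_mm
    sl = _shepp_logan(n, cfg.fov_mm, pix)

    cx_mm, cy_mm = cfg.aqueduct_center_mm
    radius_mm = cfg.aqueduct_diameter_mm / 2.0
    # aqueduct must lie fully inside the outer ellipse of the head
    a0, b0 = _SHEPP_LOGAN[0, 1] * cfg.fov_mm / 2, _SHEPP_LOGAN[0, 2] * cfg.fov_mm / 2
    for dx, dy in ((radius_mm, 0), (-radius_mm, 0), (0, radius_mm), (0, -radius_mm)):
        if ((cx_mm + dx) / a0) ** 2 + ((cy_mm + dy) / b0) ** 2 > 1.0:
            raise ValueError("aqueduct disc extends outside the scene support")

    coords_mm = (np.arange(n) - n // 2) * pix
    Xmm, Ymm = np.meshgrid(coords_mm, coords_mm)
    mask = (Xmm - cx_mm) ** 2 + (Ymm - cy_mm) ** 2 <= radius_mm**2
    if not mask.any():
        raise ValueError("aqueduct smaller than one pixel at this resolution")

    # value of the underlying tissue at the aqueduct center
    local = _shepp_logan_value(cx_mm, cy_mm, cfg.fov_mm)
    if local <= 0:
        raise ValueError("aqueduct center lies in a zero-signal region")
    img = sl * (cfg.tissue_magnitude / local)
    img[mask] = cfg.aqueduct_magnitude
    return Scene(img.astype(np.complex128), mask, pix)


def _shepp_logan_value(x_mm: float, y_mm: float, fov_mm: float) -> float:
    x, y = x_mm / (fov_mm / 2), y_mm / (fov_mm / 2)
    val = 0.0
    for inten, a, b, x0, y0, phi in _SHEPP_LOGAN:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        if (xr / a) ** 2 + (yr / b) ** 2 <= 1.0:
            val += inten
    return val


def evaluate_velocity(wf: FlowWaveform, t) -> np.ndarray:
    """Through-plane velocity v(t) in cm/s at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    f_r = wf.resp_frequency_cpm / 60.0
    f_c = wf.card_frequency_cpm / 60.0
    return wf.resp_amplitude * np.sin(
        2 * np.pi * f_r * t + wf.resp_phase
    ) + wf.card_amplitude * np.sin(2 * np.pi * f_c * t + wf.card_phase)


def velocity_to_phase(v, venc_cm_s: float, sign: int):
    """Phase (radians) contributed by one velocity encoding.

    The split is symmetric, ``sign * (pi/2) * v / VENC``, so the complex
    division of the two encodings spans a phase of pi at v = VENC.
    """
    if venc_cm_s <= 0:
        raise ValueError("venc must be > 0")
    return sign * (np.pi / 2.0) * np.asarray(v, dtype=float) / venc_cm_s


def simulate_coil_maps(n_coils: int, matrix_size: int) -> np.ndarray:
    """Deterministic smooth synthetic receive sensitivities.

    ``n_coils`` Gaussian-profile loop elements are placed evenly on a circle
    just outside the FOV; each carries a mild linear phase along its viewing
    direction plus a constant offset.  The root-sum-of-squares is bounded
    away from zero over the whole grid.  A single coil yields a uniform map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = matrix_size
    if n_coils == 1:
        return np.ones((1, n, n), dtype=np.complex128)
    idx = np.arange(n) - n // 2
    X, Y = np.meshgrid(idx, idx)
    maps = np.empty((n_coils, n, n), dtype=np.complex128)
    r_coil = 0.65 * n
    sigma = 0.55 * n
    for c in range(n_coils):
        th = 2 * np.pi * c / n_coils
        cx, cy = r_coil * np.cos(th), r_coil * np.sin(th)
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        amp = np.exp(-d2 / (2 * sigma**2))
        proj = (X * np.cos(th) + Y * np.sin(th)) / n
        maps[c] = amp * np.exp(1j * (0.6 * np.pi * proj + th))
    return maps


def simulate_kspace(
    scene: Scene,
    wf: FlowWaveform,
    maps: np.ndarray,
    acq: AcquisitionConfig,
) -> RadialKSpace:
    """Spoke-by-spoke noise-free acquisition of the phantom.

    Per TR index ``i``: simulation time ``t = i * TR``; the velocity is
    re-evaluated and converted to aqueduct phase with the encoding sign
    alternating every TR; one radial spoke is sampled from the coil-weighted
    scene.  The spoke angle advances by the golden angle every second TR, so
    both encodings of a pair share an angle.  The velocity is frozen during
    one readout.
    """
    n = scene.image.shape[0]
    if maps.shape[-2:] != (n, n):
        raise ValueError("coil maps and scene size mismatch")
    n_samples = acq.readout_samples or 2 * n
    tr_s = acq.tr_ms / 1000.0
    n_tr = int(np.floor(acq.duration_s / tr_s))
    n_pairs = n_tr // acq.n_encodings
    if n_pairs < acq.spokes_per_frame:
        raise ValueError("duration too short for a single reconstructed frame")
    n_tr = n_pairs * acq.n_encodings

    pair_angles = golden_angles(n_pairs)
    coords = np.concatenate([spoke_coords(a, n_samples) for a in pair_angles])
    plan = NufftPlan((n, n), coords, width=6, dtype=np.complex128)

    n_coils = maps.shape[0]
    static = plan.forward(maps * scene.image[None])  # (n_coils, n_pairs*n_samples)
    static = static.reshape(n_coils, n_pairs, n_samples)

    # exact direct-Fourier contribution of the aqueduct pixels per pair angle
    ys, xs = np.nonzero(scene.aqueduct_mask)
    rx = (xs - n // 2).astype(float)
    ry = (ys - n // 2).astype(float)
    aq_signal = maps[:, ys, xs] * scene.image[ys, xs][None]  # (n_coils, n_aq)
    coords3 = coords.reshape(n_pairs, n_samples, 2)
    # phase matrix per pair: (n_pairs, n_samples, n_aq)
    expo = np.exp(
        -2j
        * np.pi
        * (
            coords3[:, :, 0:1] * rx[None, None, :]
            + coords3[:, :, 1:2] * ry[None, None, :]
        )
    )

    data = np.empty((n_tr, n_samples, n_coils), dtype=np.complex128)
    times = np.arange(n_tr) * tr_s
    signs = np.where(np.arange(n_tr) % 2 == 0, 1, -1)
    v = evaluate_velocity(wf, times)
    phases = velocity_to_phase(v, acq.venc_cm_s, 1) * signs  # per-TR aqueduct phase
    for i in range(n_tr):
        p = i // acq.n_encodings
        aq = expo[p] @ aq_signal.T  # (n_samples, n_coils)
        data[i] = static[:, p, :].T + (np.exp(1j * phases[i]) - 1.0) * aq

    attrs = {
        "matrix_size": n,
        "fov_mm": n * scene.pixel_mm,
        "pixel_mm": scene.pixel_mm,
        "n_coils": n_coils,
        **{f"wf_{k}": v_ for k, v_ in asdict(wf).items()},
        **{
            f"acq_{k}": (v_ if v_ is not None else n_samples)
            for k, v_ in asdict(acq).items()
        },
    }
    angles = np.repeat(pair_angles, acq.n_encodings)
    return RadialKSpace(data, angles, times, signs, attrs)
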