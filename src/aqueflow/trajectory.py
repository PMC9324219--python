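"""Golden-angle radial k-space trajectories, density compensation and frame binning.

Conventions
-----------
* k-space coordinates are in cycles/pixel, spanning ``[-0.5, +0.5)`` along a
  spoke, with one sample exactly at k = 0.
* Spoke angles are stored in degrees, reduced modulo 360.  Spokes that differ
  by 180 degrees are geometrically equivalent (conjugate-symmetric for real
  objects) but are kept distinct in the ordering.
* Image coordinates are 0-based with the pixel-center convention; the image
  center pixel is at index ``N // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "Trajectory",
    "golden_angles",
    "spoke_coords",
    "ramlak_weights",
    "frame_bins",
]

#: Golden-angle increment in degrees: 180 / phi = 90 * (sqrt(5) - 1) = 111.24611...
GOLDEN_ANGLE_DEG: float = 90.0 * (np.sqrt(5.0) - 1.0)


@dataclass
class Trajectory:
    """Radial trajectory for a set of spokes.

    Attributes
    ----------
    angles : (n_spokes,) float array, degrees mod 360
    coords : (n_spokes, n_samples, 2) float array, cycles/pixel, (kx, ky)
    dcf : (n_samples,) float array
        Ram-Lak density-compensation weight per readout sample (shared by all
        spokes of an evenly covered set), normalized to mean 1.
    """

    angles: np.ndarray
    coords: np.ndarray
    dcf: np.ndarray

    @property
    def n_spokes(self) -> int:
        return len(self.angles)

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]


def golden_angles(n_spokes: int) -> np.ndarray:
    """Spoke angles of the golden-angle ordering, degrees mod 360.

    The increment between consecutive readout directions is
    180*(3 - sqrt(5)) = 111.246 degrees, which yields near-uniform angular
    coverage of k-space for any contiguous window of spokes.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    i = np.arange(n_spokes, dtype=float)
    return np.mod(i * GOLDEN_ANGLE_DEG, 360.0)


def spoke_coords(angle_deg: float, n_samples: int) -> np.ndarray:
    """Sample coordinates of one radial spoke, cycles/pixel.

    Returns an ``(n_samples, 2)`` array of (kx, ky).  Samples span
    ``[-0.5, +0.5)`` uniformly along the direction ``(cos a, sin a)``; the
    sample at index ``n_samples // 2`` lies exactly at k = 0.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    radii = (np.arange(n_samples) - n_samples // 2) / n_samples
    a = np.deg2rad(angle_deg)
    return np.stack([radii * np.cos(a), radii * np.sin(a)], axis=-1)


def ramlak_weights(n_samples: int, n_spokes: int | None = None) -> np.ndarray:
    """Ram-Lak (|k|) density-compensation weights along one spoke.

    The weight is proportional to the radial distance |k| of each sample,
    which compensates the 1/|k| sampling density of radial trajectories.  The
    center sample (k = 0) is shared by all spokes; it receives the finite
    weight ``ramp_step / (2 * n_spokes)`` -- the area of the small disc it
    represents divided over the spokes crossing it -- instead of zero.  With
    ``n_spokes=None`` the center weight defaults to ``ramp_step / 2`` (the
    single-spoke ramp apex), adequate whenever only relative weighting
    matters.  Weights are normalized to mean 1.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    radii = np.abs(np.arange(n_samples) - n_samples // 2) / n_samples
    w = radii.copy()
    step = 1.0 / n_samples
    center = n_samples // 2
    w[center] = step / 2.0 if n_spokes is None else step / (2.0 * n_spokes)
    return w / w.mean()


def frame_bins(
    n_spokes_per_encoding: int,
    spokes_per_frame: int,
    tr_ms: float,
    n_encodings: int = 2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bin consecutive spokes of one encoding into reconstruction frames.

    Parameters
    ----------
    n_spokes_per_encoding : total spokes acquired per velocity encoding.
    spokes_per_frame : spokes of one encoding grouped into one frame.
    tr_ms : repetition time in milliseconds (one spoke of one encoding per TR).
    n_encodings : interleaved velocity encodings sharing the timeline.

    Returns
    -------
    frame_of_spoke : (n_spokes_per_encoding,) int array
        Frame index per spoke; -1 marks spokes of a trailing partial frame,
        which is discarded.
    frame_times_s : (n_frames,) float array
        Timestamp of each frame window center, seconds from acquisition start.
    frame_duration_s : float
        ``spokes_per_frame * n_encodings * tr_ms / 1000``.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    n_frames = n_spokes_per_encoding // spokes_per_frame
    if n_frames < 1:
        raise ValueError(
            f"need at least {spokes_per_frame} spokes per encoding for one "
            f"frame, got {n_spokes_per_encoding}"
        )
    frame_of_spoke = np.arange(n_spokes_per_encoding) // spokes_per_frame
    frame_of_spoke[frame_of_spoke >= n_frames] = -1
    frame_duration_s = spokes_per_frame * n_encodings * tr_ms / 1000.0
    frame_times_s = (np.arange(n_frames) + 0.5) * frame_duration_s
    return frame_of_spoke, frame_times_s, frame_duration_s
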