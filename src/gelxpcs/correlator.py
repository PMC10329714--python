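"""Two-time correlation of coherent speckle frame series.

The central object is the two-time correlation matrix (TTC)

    c2(q, t1, t2) = <I_p(t1) I_p(t2)>_p / (<I_p(t1)>_p <I_p(t2)>_p)

where <.>_p averages over the detector pixels of an annulus (q-ring).  The
normalization uses the instantaneous per-frame pixel means, which keeps the
matrix well-behaved under slow intensity drift from beam damage.  The module
also provides the pixel-to-q mapping for a far-field detector geometry,
q-ring construction, and photon-noise-corrected speckle contrast estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorGeometry",
    "QRingSpec",
    "TwoTimeMatrix",
    "q_map",
    "build_rings",
    "ring_series_from_stack",
    "two_time",
    "contrast",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Far-field detector geometry.

    pixel_size_um : pixel pitch in micrometres
    distance_m    : sample-detector distance in metres
    wavelength_A  : X-ray wavelength in Angstrom
    beam_center   : (row, col) of the direct beam in pixel coordinates
    shape         : (n_rows, n_cols) of the detector
    """

    pixel_size_um: float
    distance_m: float
    wavelength_A: float
    beam_center: tuple
    shape: tuple

    def __post_init__(self) -> None:
        if min(self.pixel_size_um, self.distance_m, self.wavelength_A) <= 0:
            raise ValueError("geometry lengths must be positive")
        cy, cx = self.beam_center
        ny, nx = self.shape
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError("beam_center must lie within the detector frame")


def q_map(geometry: DetectorGeometry) -> np.ndarray:
    """Per-pixel momentum transfer in 1/nm.

    q = (4 pi / lambda) sin(theta/2) with tan(theta) = r / L, r the radial
    distance of the pixel from the beam centre.  At USAXS angles this reduces
    to q ~ 2 pi r / (lambda L).
    """
    ny, nx = geometry.shape
    cy, cx = geometry.beam_center
    yy, xx = np.mgrid[0:ny, 0:nx]
    r_m = np.hypot(yy - cy, xx - cx) * geometry.pixel_size_um * 1e-6
    theta = np.arctan2(r_m, geometry.distance_m)
    wavelength_nm = geometry.wavelength_A * 0.1
    return (4.0 * np.pi / wavelength_nm) * np.sin(theta / 2.0)


@dataclass(frozen=True)
class QRingSpec:
    """Annulus of pixels at momentum transfer ``q_center`` +- ``q_width``/2."""

    q_center: float
    q_width: float
    pixel_indices: np.ndarray  # flat indices into a detector frame

    def __post_init__(self) -> None:
        if len(self.pixel_indices) == 0:
            raise ValueError(f"ring at q={self.q_center} has no member pixels")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_indices)


def build_rings(qmap: np.ndarray, ring_specs, mask: np.ndarray | None = None):
    """Assign detector pixels to annuli.

    ``ring_specs`` is an iterable of (q_center, q_width); ``mask`` marks
    excluded pixels with nonzero values.  Raises if a requested ring captures
    no pixels, naming the offending ring.
    """
    flat_q = np.asarray(qmap, dtype=float).ravel()
    excluded = (
        np.zeros_like(flat_q, dtype=bool)
        if mask is None
        else np.asarray(mask).ravel() != 0
    )
    rings = []
    for q_center, q_width in ring_specs:
        inside = (
            (np.abs(flat_q - q_center) <= q_width / 2.0) & ~excluded
        )
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            raise ValueError(
                f"ring q={q_center} (width {q_width}) contains no unmasked pixels"
            )
        rings.append(QRingSpec(q_center=q_center, q_width=q_width, pixel_indices=idx))
    return rings


def ring_series_from_stack(stack, ring: QRingSpec, block: int = 256) -> np.ndarray:
    """Extract the [n_pixels, n_frames] series of a ring from a frame stack.

    ``stack`` may be an in-memory array or an h5py dataset shaped
    [n_frames, ny, nx]; frames are streamed in blocks of ``block`` so the
    full stack need not be resident.
    """
    n_frames = stack.shape[0]
    out = np.empty((ring.n_pixels, n_frames), dtype=float)
    for start in range(0, n_frames, block):
        chunk = np.asarray(stack[start : start + block], dtype=float)
        flat = chunk.reshape(chunk.shape[0], -1)
        out[:, start : start + chunk.shape[0]] = flat[:, ring.pixel_indices].T
    return out


@dataclass
class TwoTimeMatrix:
    """Two-time correlation matrix of one q-ring.

    ``values[i, j]`` is c2(t_i, t_j); symmetric, with the diagonal elevated
    by the photon-noise term.  ``dose_rate_kGy_s`` (optional) turns the time
    axis into a dose axis.
    """

    values: np.ndarray
    timestamps: np.ndarray
    ring_q: float
    n_pixels: int
    dose_rate_kGy_s: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("TTC must be square")
        if v.shape[0] != len(self.timestamps):
            raise ValueError("timestamps must match matrix size")

    @property
    def dose_axis_kGy(self) -> np.ndarray:
        """Accumulated dose at each frame time (requires a dose rate)."""
        if self.dose_rate_kGy_s is None:
            raise ValueError("no dose rate attached to this matrix")
        return np.asarray(self.timestamps, dtype=float) * self.dose_rate_kGy_s

    def with_dose(self, protocol) -> "TwoTimeMatrix":
        """Attach the dose axis of a :class:`~gelxpcs.dosimetry.DoseProtocol`."""
        return TwoTimeMatrix(
            values=self.values,
            timestamps=self.timestamps,
            ring_q=self.ring_q,
            n_pixels=self.n_pixels,
            dose_rate_kGy_s=protocol.dose_rate_kGy_s,
        )


def two_time(
    pixel_series: np.ndarray,
    timestamps=None,
    ring_q: float = np.nan,
    dose_rate_kGy_s: float | None = None,
) -> TwoTimeMatrix:
    """Two-time correlation matrix from a [n_pixels, n_frames] series.

    Normalizes by the instantaneous per-frame pixel means; any frame with
    zero mean intensity in the ring raises (the normalization would divide
    by zero).  The result is symmetrized, which removes the floating-point
    asymmetry of the underlying matrix product.
    """
    x = np.asarray(pixel_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("pixel_series must be [n_pixels, n_frames]")
    n_px, n_frames = x.shape
    if n_frames < 2:
        raise ValueError("need at least two frames")
    means = x.mean(axis=0)
    if np.any(means == 0):
        bad = int(np.flatnonzero(means == 0)[0])
        raise ValueError(f"frame {bad} has zero mean intensity in the ring")
    corr = (x.T @ x) / n_px / np.outer(means, means)
    corr = 0.5 * (corr + corr.T)
    if timestamps is None:
        timestamps = np.arange(n_frames, dtype=float)
    return TwoTimeMatrix(
        values=corr,
        timestamps=np.asarray(timestamps, dtype=float),
        ring_q=float(ring_q),
        n_pixels=n_px,
        dose_rate_kGy_s=dose_rate_kGy_s,
    )


def contrast(pixel_series: np.ndarray, n_frames_avg: int = 50) -> float:
    """Speckle contrast estimate, corrected for Poisson photon noise.

    For photon counts n with underlying intensity I, the normalized variance
    across pixels is Var(n)/<n>^2 = beta + 1/<n>; subtracting the shot-noise
    term 1/<n> per frame leaves the speckle contrast beta.  Averaged over the
    first ``n_frames_avg`` frames, where the sample is least damaged.
    """
    x = np.asarray(pixel_series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("pixel_series must be [n_pixels, n_frames]")
    x = x[:, : max(1, min(n_frames_avg, x.shape[1]))]
    means = x.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("zero mean count; cannot normalize")
    norm_var = x.var(axis=0, ddof=1) / means**2
    return float(np.mean(norm_var - 1.0 / means))
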