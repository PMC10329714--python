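"""Seeded synthetic coherent-speckle data with known ground truth.

The generator realizes, microscopically, the statistical structure the
analysis chain assumes, so that every downstream stage (correlator, KWW
fits, threshold analyses) can be validated against programmed parameters:

* point scatterers whose positions evolve by discrete stress-relaxation
  events: events arrive as a Poisson process at rate ``gamma`` and each
  event displaces a scatterer by its own frozen displacement vector (drawn
  once per scatterer from an isotropic Gaussian with per-axis standard
  deviation sqrt(2)*delta).  The persistence of the direction makes the
  displacement accumulate ballistically with the event count N, which is
  what produces the compressed-exponential (k in [1.5, 2]) decorrelation
  exp(-(q N delta)^2) of stress-relaxation dynamics; redrawing the
  direction at every event would instead give an uncorrelated random walk
  and a simple exponential.
* optional ballistic drift: a frozen per-scatterer velocity field (per-axis
  std sqrt(2)*v), giving Gamma = v*q with k = 2 — the operational meaning of
  the XPCS "velocity" v = Gamma/q.
* optional diffusion with coefficient D (per-axis variance 2*D*dt per
  frame), giving Gamma ~ D*q^2 with k = 1.
* fully-coherent speckle per mode: each detector pixel in a q-ring carries
  a random scattering vector of magnitude q; the field is the coherent sum
  over scatterers, so with many scatterers the intensity statistics are
  negative-exponential (contrast 1).  Partial contrast beta is realized by
  averaging M = round(1/beta) independent speckle modes.
* photon counting: Poisson draws with mean proportional to the intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .correlator import DetectorGeometry, build_rings, q_map

__all__ = [
    "SyntheticConfig",
    "RingIntensitySeries",
    "FrameSeries",
    "StaticDamageParams",
    "StaticIntensityTable",
    "simulate_event_dynamics",
    "simulate_dose_response",
    "simulate_static_intensity",
    "frames_from_rings",
    "write_frames",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the microscopic speckle simulation.

    Rates are per second, lengths in nm, q in 1/nm.  ``contrast`` is the
    target speckle contrast beta in (0, 1]; it is realized as 1/M with
    M = round(1/beta) independent modes.
    """

    n_scatterers: int = 48
    box_size_nm: float = 2000.0
    event_rate: float = 0.0  # gamma, 1/s
    step_size_nm: float = 0.0  # delta
    drift_speed_nm_s: float = 0.0  # v
    diffusion_nm2_s: float = 0.0  # D
    q_rings: tuple = (0.006, 0.02, 0.06)
    pixels_per_ring: int = 2000
    contrast: float = 0.1
    mean_counts_per_pixel: float = 50.0
    frame_interval_s: float = 1.0
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must be in (0, 1]")
        for name in ("event_rate", "drift_speed_nm_s", "diffusion_nm2_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_scatterers < 1 or self.pixels_per_ring < 1 or self.n_frames < 1:
            raise ValueError("sizes must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_modes(self) -> int:
        m = int(round(1.0 / self.contrast))
        if m < 1:
            raise ValueError("contrast implies fewer than one speckle mode")
        return m


@dataclass
class RingIntensitySeries:
    """Photon-count series per q-ring: one [n_pixels, n_frames] block each."""

    ring_q: tuple
    counts: list  # list of integer arrays [n_pixels, n_frames]
    timestamps: np.ndarray
    config: SyntheticConfig
    event_rate_per_frame: np.ndarray | None = None

    def series(self, q: float) -> np.ndarray:
        """Counts of the ring whose q matches ``q``."""
        idx = int(np.argmin(np.abs(np.asarray(self.ring_q) - q)))
        if not math.isclose(self.ring_q[idx], q, rel_tol=1e-6):
            raise KeyError(f"no ring at q={q}; available: {self.ring_q}")
        return self.counts[idx]


def _isotropic_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _simulate(config: SyntheticConfig, gamma_per_frame: np.ndarray) -> RingIntensitySeries:
    rng = np.random.default_rng(config.seed)
    m = config.n_modes
    ns = config.n_scatterers
    dt = config.frame_interval_s
    nf = config.n_frames

    # per-pixel scattering vectors, all rings stacked
    q_all = []
    for q in config.q_rings:
        q_all.append(q * _isotropic_unit_vectors(rng, config.pixels_per_ring))
    q_vectors = np.concatenate(q_all, axis=0)  # [n_pix_total, 3]

    positions = rng.uniform(0.0, config.box_size_nm, size=(m, ns, 3))
    event_step = rng.normal(0.0, math.sqrt(2.0) * config.step_size_nm, size=(m, ns, 3))
    velocity = rng.normal(0.0, math.sqrt(2.0) * config.drift_speed_nm_s, size=(m, ns, 3))
    diff_sigma = math.sqrt(2.0 * config.diffusion_nm2_s * dt)

    static = (
        np.all(gamma_per_frame == 0.0)
        and config.drift_speed_nm_s == 0.0
        and config.diffusion_nm2_s == 0.0
    )

    n_pix_total = q_vectors.shape[0]
    counts = np.empty((n_pix_total, nf), dtype=np.uint32)
    intensity = None
    for i in range(nf):
        if i > 0 and not static:
            n_events = rng.poisson(gamma_per_frame[i] * dt, size=(m, ns))
            positions = positions + n_events[..., None] * event_step + velocity * dt
            if diff_sigma > 0:
                positions = positions + rng.normal(0.0, diff_sigma, size=(m, ns, 3))
        if intensity is None or not static:
            # phases [m, ns, n_pix]; coherent sum over scatterers per mode
            phases = positions @ q_vectors.T
            fields = np.exp(1j * phases).sum(axis=1)
            intensity = (np.abs(fields) ** 2 / ns).mean(axis=0)
        counts[:, i] = rng.poisson(config.mean_counts_per_pixel * intensity)

    per_ring = np.split(counts, np.cumsum([config.pixels_per_ring] * (len(config.q_rings) - 1)))
    return RingIntensitySeries(
        ring_q=tuple(config.q_rings),
        counts=[np.ascontiguousarray(c) for c in per_ring],
        timestamps=np.arange(nf, dtype=float) * dt,
        config=config,
        event_rate_per_frame=np.asarray(gamma_per_frame, dtype=float),
    )


def simulate_event_dynamics(config: SyntheticConfig) -> RingIntensitySeries:
    """Simulate speckle series with a constant stress-relaxation event rate."""
    gamma = np.full(config.n_frames, float(config.event_rate))
    return _simulate(config, gamma)


def simulate_dose_response(
    config: SyntheticConfig, protocol, response
) -> RingIntensitySeries:
    """Simulate with an event rate modulated by the accumulated dose.

    ``response`` maps dose (kGy) to a non-negative multiplier on the base
    event rate; evaluated at each frame time using the protocol's dose rate.
    Supports piecewise schedules (e.g. absorber changes mid-scan) via any
    callable of the dose.
    """
    times = np.arange(config.n_frames, dtype=float) * config.frame_interval_s
    doses = protocol.dose_at(times)
    mult = np.asarray([float(response(d)) for d in doses])
    if np.any(mult < 0):
        raise ValueError("dose response multiplier must be non-negative")
    return _simulate(config, config.event_rate * mult)


@dataclass(frozen=True)
class StaticDamageParams:
    """Parametric structural-damage curve for the relative intensity I/I0.

    Flat at 1 until ``onset_kGy``, then a saturating rise of relative
    ``amplitude`` on the dose scale ``rise_scale_kGy``; an optional slow
    decay (``decay_scale_kGy``) makes the curve turn over at high dose,
    as fluidized gels re-aggregate.
    """

    onset_kGy: float = 5.0
    amplitude: float = 0.5
    rise_scale_kGy: float = 20.0
    decay_scale_kGy: float | None = None
    sign: float = 1.0  # +1 intensity rises (soft gels), -1 falls (strong gels)

    def curve(self, dose_kGy) -> np.ndarray:
        d = np.asarray(dose_kGy, dtype=float)
        x = np.clip(d - self.onset_kGy, 0.0, None)
        rise = self.amplitude * (1.0 - np.exp(-x / self.rise_scale_kGy))
        if self.decay_scale_kGy is not None:
            rise = rise * np.exp(-x / self.decay_scale_kGy)
        return 1.0 + self.sign * rise

    def true_threshold(self, criterion: float = 0.01) -> float | None:
        """Dose where |I/I0 - 1| first exceeds ``criterion`` (noiseless).

        Closed form for the monotonic rise; solved on a dense grid when a
        decay term makes the curve non-monotonic.
        """
        if self.amplitude <= criterion:
            return None
        if self.decay_scale_kGy is None:
            return self.onset_kGy - self.rise_scale_kGy * math.log(
                1.0 - criterion / self.amplitude
            )
        span = self.onset_kGy + 20.0 * self.rise_scale_kGy
        d = np.linspace(0.0, span, 200001)
        above = np.abs(self.curve(d) - 1.0) > criterion
        if not above.any():
            return None
        return float(d[int(np.argmax(above))])


@dataclass
class StaticIntensityTable:
    """q-resolved scattered-intensity table I(q, t) with damage ground truth."""

    q_values: np.ndarray
    times: np.ndarray
    values: np.ndarray  # [n_q, n_t]
    damage: StaticDamageParams
    dose_rate_kGy_s: float | None = None

    @property
    def doses_kGy(self) -> np.ndarray:
        if self.dose_rate_kGy_s is None:
            raise ValueError("no dose rate attached")
        return self.times * self.dose_rate_kGy_s


def simulate_static_intensity(
    dose_axis_kGy,
    damage: StaticDamageParams,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    q_values=None,
    dose_rate_kGy_s: float = 1.0,
) -> StaticIntensityTable:
    """Synthesize an azimuthally-averaged intensity table under beam damage.

    The damage factor multiplies a q^-2 baseline uniformly across q (the
    analysis averages over a q-interval anyway); multiplicative noise of
    relative level ``noise_sigma`` is applied per time point, shared across
    q, so it survives q-averaging unchanged.
    """
    doses = np.asarray(dose_axis_kGy, dtype=float)
    if doses.ndim != 1 or len(doses) < 2 or np.any(np.diff(doses) <= 0):
        raise ValueError("dose axis must be 1-D and strictly increasing")
    if q_values is None:
        q_values = np.geomspace(0.005, 0.05, 24)
    q_values = np.asarray(q_values, dtype=float)
    baseline = q_values ** -2.0
    curve = damage.curve(doses)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        curve = curve * (1.0 + noise_sigma * rng.standard_normal(len(doses)))
    values = baseline[:, None] * curve[None, :]
    return StaticIntensityTable(
        q_values=q_values,
        times=doses / dose_rate_kGy_s,
        values=values,
        damage=damage,
        dose_rate_kGy_s=dose_rate_kGy_s,
    )


@dataclass
class FrameSeries:
    """Detector frame stack [n_frames, ny, nx] with timestamps and geometry."""

    frames: np.ndarray
    timestamps: np.ndarray
    geometry: DetectorGeometry

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be [n_frames, ny, nx]")
        if len(self.timestamps) != self.frames.shape[0]:
            raise ValueError("timestamps must match the number of frames")
        if len(self.timestamps) == 0:
            raise ValueError("empty frame series")


def frames_from_rings(
    series: RingIntensitySeries,
    geometry: DetectorGeometry,
    q_width_rel: float = 0.1,
    background_counts: float = 1.0,
):
    """Embed per-ring pixel series into detector frames.

    Ring members are the geometry pixels whose computed q falls within
    ``q_width_rel * q`` of each ring q; the simulated pixel series fill the
    first members (raises if a ring is narrower than the simulation), the
    rest of the detector is incoherent Poisson background.  Returns the
    FrameSeries and the ring specs needed to read the data back losslessly.
    """
    qmap = q_map(geometry)
    specs = [(q, q_width_rel * q) for q in series.ring_q]
    rings = build_rings(qmap, specs)
    rng = np.random.default_rng(series.config.seed + 1)
    nf = len(series.timestamps)
    ny, nx = geometry.shape
    frames = rng.poisson(background_counts, size=(nf, ny * nx)).astype(np.uint32)
    for ring, counts in zip(rings, series.counts):
        n_sim = counts.shape[0]
        if ring.n_pixels < n_sim:
            raise ValueError(
                f"ring q={ring.q_center} has {ring.n_pixels} detector pixels "
                f"but the simulation provides {n_sim}; enlarge the geometry"
            )
        frames[:, ring.pixel_indices[:n_sim]] = counts.T
    return (
        FrameSeries(
            frames=frames.reshape(nf, ny, nx),
            timestamps=np.asarray(series.timestamps, dtype=float),
            geometry=geometry,
        ),
        rings,
    )


def write_frames(frame_series: FrameSeries, path, overwrite: bool = False) -> None:
    """Persist a frame series to the HDF5 stack layout.

    Layout: /entry/data/data [n_frames, ny, nx] (uint), /entry/data/timestamps
    [n_frames] (s), and a geometry group with pixel_size_um, distance_m,
    wavelength_A and beam_center attributes.
    """
    import os

    import h5py

    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    geo = frame_series.geometry
    with h5py.File(path, "w") as fh:
        data = fh.create_group("entry/data")
        data.create_dataset("data", data=frame_series.frames, dtype=np.uint32)
        data.create_dataset("timestamps", data=np.asarray(frame_series.timestamps, float))
        g = fh.create_group("entry/geometry")
        g.attrs["pixel_size_um"] = geo.pixel_size_um
        g.attrs["distance_m"] = geo.distance_m
        g.attrs["wavelength_A"] = geo.wavelength_A
        g.attrs["beam_center"] = list(geo.beam_center)
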