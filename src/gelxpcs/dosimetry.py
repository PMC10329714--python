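"""Synchrotron dosimetry for water-equivalent gel samples.

Converts beamline parameters (photon flux, energy, silicon-wafer absorbers,
sample geometry) into the quantities that label an XPCS scan: photon fluence
on the sample, absorbed dose rate, accumulated dose, and order-of-magnitude
radiolysis rates.

The absorbed-dose model is the standard thin-sample calorimetric estimate

    dose_rate = F_red * E * (1 - T) / (V * rho)

with ``F_red`` the absorber-reduced flux, ``E`` the photon energy, ``T`` the
sample transmission, ``V`` the illuminated volume and ``rho`` the mass density
of the water equivalent.  Absorbers are stacks of 25 um silicon wafers; each
wafer transmits a fixed fraction (73% at 8.54 keV), so ``n`` wafers reduce the
flux by ``0.73**n``.  Flux-reducing effects of the capillary walls are not
taken into account.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamConfig",
    "SampleGeometry",
    "AttenuationTable",
    "DoseProtocol",
    "RadiolysisEstimate",
    "WATER_ATTENUATION",
    "reduced_flux",
    "fluence",
    "dose_rate",
    "accumulated_dose",
    "water_transmission",
    "radical_rate",
]

EV_TO_J = 1.602176634e-19
WATER_DENSITY_G_CM3 = 1.0

#: Absorber counts realizable by the beamline absorber unit (stacks of
#: 25 um Si wafers come in fixed combinations, so only certain n occur).
STANDARD_ABSORBER_INDICES = frozenset({0, 1, 2, 4, 6, 8, 12, 16, 18, 24})


@dataclass(frozen=True)
class BeamConfig:
    """Unattenuated beam parameters at the sample position.

    Parameters
    ----------
    flux_unattenuated : float
        Photon flux with no absorber, ph/s.
    photon_energy_keV : float
        Photon energy in keV.
    beam_width_um, beam_height_um : float
        Beam footprint on the sample, micrometres.
    wafer_transmission : float
        Transmission of a single 25 um Si wafer at the working energy.
    allowed_absorber_indices : frozenset[int]
        Absorber counts the attenuation unit can realize.  Other values are
        accepted with a warning.
    """

    flux_unattenuated: float
    photon_energy_keV: float
    beam_width_um: float
    beam_height_um: float
    wafer_transmission: float = 0.73
    allowed_absorber_indices: frozenset = STANDARD_ABSORBER_INDICES

    def __post_init__(self) -> None:
        if self.flux_unattenuated < 0:
            raise ValueError("flux_unattenuated must be non-negative")
        if self.photon_energy_keV <= 0:
            raise ValueError("photon_energy_keV must be positive")
        if not 0.0 < self.wafer_transmission < 1.0:
            raise ValueError("wafer_transmission must be in (0, 1)")
        if self.beam_width_um < 0 or self.beam_height_um < 0:
            raise ValueError("beam dimensions must be non-negative")

    @property
    def beam_area_nm2(self) -> float:
        """Beam footprint in nm^2 (1 um = 1e3 nm)."""
        return (self.beam_width_um * 1e3) * (self.beam_height_um * 1e3)

    @property
    def photon_energy_eV(self) -> float:
        return self.photon_energy_keV * 1e3

    @property
    def photon_energy_J(self) -> float:
        return self.photon_energy_eV * EV_TO_J


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass attenuation coefficient on an energy grid.

    ``coefficients`` are mu/rho values in cm^2/g at ``energies_keV``.
    Interpolation is log-log, the standard behaviour of attenuation data,
    and queries outside the grid raise rather than extrapolate.
    """

    energies_keV: tuple
    coefficients_cm2_g: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        mu = np.asarray(self.coefficients_cm2_g, dtype=float)
        if e.ndim != 1 or e.shape != mu.shape or e.size < 2:
            raise ValueError("energy grid and coefficients must be 1-D and matched")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(mu > 0):
            raise ValueError("attenuation coefficients must be strictly positive")

    def mass_attenuation(self, energy_keV: float) -> float:
        """mu/rho (cm^2/g) at ``energy_keV`` by log-log interpolation."""
        e = np.asarray(self.energies_keV, dtype=float)
        if not (e[0] <= energy_keV <= e[-1]):
            raise ValueError(
                f"energy {energy_keV} keV outside tabulated grid "
                f"[{e[0]}, {e[-1]}] keV; refusing to extrapolate"
            )
        mu = np.asarray(self.coefficients_cm2_g, dtype=float)
        return float(np.exp(np.interp(math.log(energy_keV), np.log(e), np.log(mu))))


#: Mass attenuation coefficient of liquid water, cm^2/g, on the standard
#: 5-20 keV grid (tabulated photon cross-section data).
WATER_ATTENUATION = AttenuationTable(
    energies_keV=(5.0, 6.0, 8.0, 10.0, 15.0, 20.0),
    coefficients_cm2_g=(42.69, 24.64, 10.37, 5.329, 1.673, 0.8096),
)


def water_transmission(
    thickness_mm: float,
    energy_keV: float,
    table: AttenuationTable = WATER_ATTENUATION,
) -> float:
    """Beer-Lambert transmission of a water layer.

    Returns exp(-(mu/rho) * rho_water * thickness).  For 1.5 mm of water at
    8.54 keV this evaluates to ~0.278.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be non-negative")
    if thickness_mm == 0:
        return 1.0
    mu_rho = table.mass_attenuation(energy_keV)
    thickness_cm = thickness_mm * 0.1
    return math.exp(-mu_rho * WATER_DENSITY_G_CM3 * thickness_cm)


@dataclass(frozen=True)
class SampleGeometry:
    """Sample slab in the beam: thickness, density and X-ray transmission.

    ``transmission`` may be given directly (e.g. measured) or left ``None``
    to be computed from the bundled water attenuation data via
    :meth:`resolve_transmission`.
    """

    thickness_mm: float
    density_kg_m3: float = 1000.0
    transmission: float | None = None

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness must be positive")
        if self.density_kg_m3 <= 0:
            raise ValueError("density must be positive")
        if self.transmission is not None and not 0.0 < self.transmission < 1.0:
            raise ValueError("transmission must be in (0, 1)")

    def resolve_transmission(self, energy_keV: float) -> float:
        """Supplied transmission, or water-equivalent Beer-Lambert value."""
        if self.transmission is not None:
            return self.transmission
        return water_transmission(self.thickness_mm, energy_keV)

    def illuminated_volume_m3(self, beam: BeamConfig) -> float:
        """Illuminated volume = beam area x thickness, in m^3."""
        v = (beam.beam_width_um * 1e-6) * (beam.beam_height_um * 1e-6) * (
            self.thickness_mm * 1e-3
        )
        if v <= 0:
            raise ValueError("illuminated volume must be positive")
        return v

    @property
    def thickness_nm(self) -> float:
        return self.thickness_mm * 1e6


@dataclass(frozen=True)
class DoseProtocol:
    """One scan's irradiation conditions: beam, sample, absorber, timing."""

    beam: BeamConfig
    sample: SampleGeometry
    absorber_index: int = 0
    exposure_time_s: float = 1.0
    frame_interval_s: float = 1.0
    n_frames: int = 1

    def __post_init__(self) -> None:
        if self.exposure_time_s <= 0:
            raise ValueError("exposure_time_s must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        _check_absorber_index(self.beam, self.absorber_index)

    @property
    def reduced_flux(self) -> float:
        return reduced_flux(self.beam, self.absorber_index)

    @property
    def fluence(self) -> float:
        return fluence(self.beam, self.absorber_index)

    @property
    def dose_rate_kGy_s(self) -> float:
        return dose_rate(self)

    def dose_at(self, elapsed_s) -> float | np.ndarray:
        return accumulated_dose(self, elapsed_s)


def _check_absorber_index(beam: BeamConfig, n: int) -> None:
    if n < 0 or int(n) != n:
        raise ValueError(f"absorber index must be a non-negative integer, got {n!r}")
    if beam.allowed_absorber_indices and n not in beam.allowed_absorber_indices:
        warnings.warn(
            f"absorber index n={n} is not among the combinations the absorber "
            f"unit realizes {sorted(beam.allowed_absorber_indices)}",
            stacklevel=3,
        )


def reduced_flux(beam: BeamConfig, n: int) -> float:
    """Flux behind ``n`` stacked 25 um Si wafers: F0 * wafer_transmission**n."""
    _check_absorber_index(beam, n)
    return beam.flux_unattenuated * beam.wafer_transmission ** n


def fluence(beam: BeamConfig, n: int) -> float:
    """Photon fluence on the sample, ph/s/nm^2 (reduces like the flux)."""
    area = beam.beam_area_nm2
    if area <= 0:
        raise ValueError("beam area must be positive to define a fluence")
    return reduced_flux(beam, n) / area


def dose_rate(protocol: DoseProtocol) -> float:
    """Absorbed dose rate in kGy/s for the protocol's absorber setting.

    dose_rate = F_red * E * (1 - T) / (V * rho), with the sample treated as
    its water equivalent.
    """
    beam = protocol.beam
    sample = protocol.sample
    t = sample.resolve_transmission(beam.photon_energy_keV)
    mass_kg = sample.illuminated_volume_m3(beam) * sample.density_kg_m3
    if mass_kg == 0:
        raise ValueError("illuminated mass is zero")
    power_absorbed_W = protocol.reduced_flux * beam.photon_energy_J * (1.0 - t)
    return power_absorbed_W / mass_kg / 1e3  # Gy/s -> kGy/s


def accumulated_dose(protocol: DoseProtocol, elapsed_s) -> float | np.ndarray:
    """Dose accumulated after ``elapsed_s`` seconds of exposure, in kGy."""
    elapsed = np.asarray(elapsed_s, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed time must be non-negative")
    out = dose_rate(protocol) * elapsed
    return float(out) if np.isscalar(elapsed_s) else out


@dataclass(frozen=True)
class RadiolysisEstimate:
    """Radical production rate per unit volume and the equivalent cube.

    ``cube_edge_nm`` is the edge length of the cube in which one radical is
    produced per second; ``None`` when the rate vanishes.
    """

    fluence: float
    radical_yield_per_eV: float
    rate_per_volume: float  # radicals / s / nm^3
    cube_edge_nm: float | None

    def __post_init__(self) -> None:
        if self.rate_per_volume < 0:
            raise ValueError("rate must be non-negative")
        if self.cube_edge_nm is not None and self.cube_edge_nm <= 0:
            raise ValueError("cube edge must be positive when defined")


def radical_rate(
    fluence_ph_s_nm2: float,
    sample: SampleGeometry,
    energy_keV: float,
    radical_yield_per_eV: float = 3.0 / 100.0,
) -> RadiolysisEstimate:
    """Volumetric OH-radical production rate from water radiolysis.

    Uses the standard radiolysis yield of ~3 OH radicals per 100 eV absorbed.
    The absorbed energy per unit illuminated volume and time is
    ``fluence * (1 - T) * E / thickness``, giving

        rate = fluence * (1 - T) * E_eV * yield / thickness_nm

    in radicals/s/nm^3, and cube_edge = rate**(-1/3).
    """
    if fluence_ph_s_nm2 < 0:
        raise ValueError("fluence must be non-negative")
    t = sample.resolve_transmission(energy_keV)
    rate = (
        fluence_ph_s_nm2
        * (1.0 - t)
        * (energy_keV * 1e3)
        * radical_yield_per_eV
        / sample.thickness_nm
    )
    edge = rate ** (-1.0 / 3.0) if rate > 0 else None
    return RadiolysisEstimate(
        fluence=fluence_ph_s_nm2,
        radical_yield_per_eV=radical_yield_per_eV,
        rate_per_volume=rate,
        cube_edge_nm=edge,
    )


def dose_table(
    beam: BeamConfig,
    sample: SampleGeometry,
    indices=None,
):
    """Per-absorber summary (n, flux, fluence, dose rate) as a DataFrame.

    Mirrors the standard beamline bookkeeping table; ``indices`` defaults to
    the beam's allowed absorber set.
    """
    import pandas as pd

    if indices is None:
        indices = sorted(beam.allowed_absorber_indices)
    rows = []
    for n in indices:
        proto = DoseProtocol(beam=beam, sample=sample, absorber_index=n)
        rows.append(
            {
                "n": n,
                "flux_ph_s": proto.reduced_flux,
                "fluence_ph_s_nm2": proto.fluence,
                "dose_rate_kGy_s": proto.dose_rate_kGy_s,
            }
        )
    return pd.DataFrame(rows)
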