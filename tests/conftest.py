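import numpy as np
import pytest

from gelxpcs import (
    BeamConfig,
    DoseProtocol,
    SampleGeometry,
    SyntheticConfig,
    simulate_event_dynamics,
)


@pytest.fixture(scope="session")
def beam():
    """Reference USAXS beam: 6e10 ph/s, 8.54 keV, 100x100 um^2 footprint."""
    return BeamConfig(
        flux_unattenuated=6e10,
        photon_energy_keV=8.54,
        beam_width_um=100.0,
        beam_height_um=100.0,
    )


@pytest.fixture(scope="session")
def sample():
    """1.5 mm water-equivalent capillary; transmission computed (~27.8%)."""
    return SampleGeometry(thickness_mm=1.5)


@pytest.fixture(scope="session")
def full_beam_protocol(beam, sample):
    return DoseProtocol(beam=beam, sample=sample, absorber_index=0)


@pytest.fixture(scope="session")
def frozen_series():
    """Static fully-coherent speckle, high counts: c2 off-diagonal ~ 2."""
    config = SyntheticConfig(
        n_scatterers=256,
        event_rate=0.0,
        step_size_nm=1e-6,
        q_rings=(0.02,),
        pixels_per_ring=2000,
        contrast=1.0,
        mean_counts_per_pixel=200.0,
        n_frames=30,
        seed=42,
    )
    return simulate_event_dynamics(config)


@pytest.fixture(scope="session")
def event_series():
    """Stress-relaxation dynamics: gamma=1/s, q*delta=0.05, full coherence."""
    gamma, qdelta, q = 1.0, 0.05, 0.02
    config = SyntheticConfig(
        n_scatterers=128,
        event_rate=gamma,
        step_size_nm=qdelta / q,
        q_rings=(q,),
        pixels_per_ring=800,
        contrast=1.0,
        mean_counts_per_pixel=50.0,
        frame_interval_s=1.0,
        n_frames=200,
        seed=7,
    )
    return simulate_event_dynamics(config)
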