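"""Synthetic speckle generator: statistics, ground-truth recovery, I/O."""

import numpy as np
import pytest

from gelxpcs import correlator as corr
from gelxpcs import kww
from gelxpcs import synthetic as syn
from gelxpcs.pipeline import read_frames


def small_config(**overrides):
    base = dict(
        n_scatterers=64,
        event_rate=1.0,
        step_size_nm=2.5,
        q_rings=(0.02,),
        pixels_per_ring=400,
        contrast=1.0,
        mean_counts_per_pixel=50.0,
        frame_interval_s=1.0,
        n_frames=150,
        seed=0,
    )
    base.update(overrides)
    return syn.SyntheticConfig(**base)


class TestStatistics:
    def test_seeded_runs_are_bit_reproducible(self):
        a = syn.simulate_event_dynamics(small_config(n_frames=40))
        b = syn.simulate_event_dynamics(small_config(n_frames=40))
        assert np.array_equal(a.counts[0], b.counts[0])

    def test_different_seeds_differ(self):
        a = syn.simulate_event_dynamics(small_config(n_frames=40, seed=1))
        b = syn.simulate_event_dynamics(small_config(n_frames=40, seed=2))
        assert not np.array_equal(a.counts[0], b.counts[0])

    def test_negative_exponential_intensity_at_full_coherence(self, frozen_series):
        """beta=1, high counts: the pixel histogram is near-exponential.

        An exponential distribution has variance = mean^2 and a mode at 0;
        check the normalized variance and the quartile structure.
        """
        x = frozen_series.counts[0][:, 0].astype(float)
        mean = x.mean()
        norm_var = x.var() / mean**2 - 1.0 / mean  # shot noise removed
        assert norm_var == pytest.approx(1.0, rel=0.12)
        # exponential: P(X < mean) = 1 - 1/e ~ 0.632
        assert np.mean(x < mean) == pytest.approx(0.632, abs=0.05)

    def test_counts_are_integers(self):
        series = syn.simulate_event_dynamics(small_config(n_frames=10))
        assert series.counts[0].dtype.kind == "u"

    def test_contrast_below_one_mode_rejected(self):
        with pytest.raises(ValueError):
            small_config(contrast=1.5)


class TestEventDynamicsGroundTruth:
    def test_frozen_sample_stays_correlated(self, frozen_series):
        ttc = corr.two_time(frozen_series.counts[0])
        n = ttc.values.shape[0]
        off = ttc.values[np.triu_indices(n, k=1)]
        assert off.mean() == pytest.approx(2.0, rel=0.05)
        assert off.std() < 0.2

    def test_event_dynamics_match_analytic_model(self, event_series):
        """Fitted (k, Gamma) agree with the Poisson-Gaussian model at the
        same (gamma, q*delta): the generator and the analytic curve are
        independent realizations of the same physics."""
        from gelxpcs import event_model as em

        gamma, qdelta = 1.0, 0.05
        x = event_series.counts[0]
        ttc = corr.two_time(x, timestamps=event_series.timestamps)
        beta_hat = corr.contrast(x, n_frames_avg=10)
        fit = kww.fit_kww(
            kww.extract_g2(ttc, t2=0.0, band_width=5), fix_contrast=beta_hat
        )
        assert fit.converged
        k_model, rate_model = em.kww_map(
            em.EventModelParams(event_rate=gamma, step_size=qdelta, wavevector=1.0)
        )
        assert fit.decay_rate == pytest.approx(rate_model, rel=0.30)
        assert fit.exponent == pytest.approx(k_model, abs=0.45)
        assert 1.4 <= fit.exponent <= 2.4

    def test_drift_mode_gives_ballistic_scaling(self):
        v = 2.0
        config = small_config(
            event_rate=0.0,
            step_size_nm=1.0,
            drift_speed_nm_s=v,
            q_rings=(0.006, 0.012, 0.02),
            pixels_per_ring=600,
            n_scatterers=96,
            frame_interval_s=2.0,
            n_frames=220,
            seed=11,
        )
        series = syn.simulate_event_dynamics(config)
        fits = []
        for q, block in zip(series.ring_q, series.counts):
            ttc = corr.two_time(block, timestamps=series.timestamps)
            f = kww.fit_kww(
                kww.extract_g2(ttc, t2=0.0, band_width=5),
                fix_contrast=corr.contrast(block, 10),
            )
            fits.append((q, f.decay_rate))
        scaling = kww.q_scaling(fits)
        assert scaling.regime == "ballistic"
        assert scaling.velocity == pytest.approx(v, rel=0.15)

    def test_diffusive_mode_gives_q_squared_scaling(self):
        config = small_config(
            event_rate=0.0,
            step_size_nm=1.0,
            diffusion_nm2_s=100.0,
            q_rings=(0.02, 0.04, 0.06),
            pixels_per_ring=600,
            n_scatterers=96,
            frame_interval_s=1.0,
            n_frames=220,
            seed=12,
        )
        series = syn.simulate_event_dynamics(config)
        fits = []
        for q, block in zip(series.ring_q, series.counts):
            ttc = corr.two_time(block, timestamps=series.timestamps)
            f = kww.fit_kww(
                kww.extract_g2(ttc, t2=0.0, band_width=5),
                fix_contrast=corr.contrast(block, 10),
            )
            fits.append((q, f.decay_rate))
        scaling = kww.q_scaling(fits)
        assert scaling.regime == "diffusive"
        assert scaling.exponent == pytest.approx(2.0, abs=0.25)


class TestDoseResponse:
    def test_unit_response_reproduces_constant_rate(self, full_beam_protocol):
        config = small_config(n_frames=40)
        a = syn.simulate_event_dynamics(config)
        b = syn.simulate_dose_response(config, full_beam_protocol, lambda d: 1.0)
        assert np.array_equal(a.counts[0], b.counts[0])

    def test_negative_multiplier_rejected(self, full_beam_protocol):
        with pytest.raises(ValueError):
            syn.simulate_dose_response(
                small_config(n_frames=10), full_beam_protocol, lambda d: -1.0
            )

    def test_step_speedup_shrinks_decorrelation_width(self, beam, sample):
        """A x10 event-rate step above a dose D* shows up as a x10 faster
        decay in cuts taken after the crossing."""
        from gelxpcs import DoseProtocol

        protocol = DoseProtocol(beam=beam, sample=sample, absorber_index=0)
        rate = protocol.dose_rate_kGy_s  # ~4 kGy/s
        d_star = 100.0 * rate  # crossed at t = 100 s
        config = small_config(
            event_rate=0.2, n_frames=400, pixels_per_ring=600, seed=21
        )
        series = syn.simulate_dose_response(
            config, protocol, lambda d: 10.0 if d > d_star else 1.0
        )
        ttc = corr.two_time(series.counts[0], timestamps=series.timestamps)
        early = kww.fit_kww(kww.extract_g2(ttc, t2=0.0, max_lag=95.0, band_width=3))
        late = kww.fit_kww(kww.extract_g2(ttc, t2=250.0, band_width=3))
        assert early.converged and late.converged
        ratio = late.decay_rate / early.decay_rate
        assert 4.0 < ratio < 25.0


class TestStaticIntensity:
    def test_zero_amplitude_is_flat_with_no_threshold(self):
        damage = syn.StaticDamageParams(onset_kGy=5.0, amplitude=0.0)
        doses = np.linspace(0.1, 50.0, 100)
        table = syn.simulate_static_intensity(doses, damage)
        assert np.allclose(table.values / table.values[:, :1], 1.0)
        assert damage.true_threshold(0.01) is None

    def test_noiseless_threshold_matches_analytic_inversion(self):
        damage = syn.StaticDamageParams(
            onset_kGy=5.0, amplitude=0.5, rise_scale_kGy=20.0
        )
        expected = 5.0 - 20.0 * np.log(1.0 - 0.01 / 0.5)
        assert damage.true_threshold(0.01) == pytest.approx(expected, rel=1e-9)

    def test_decaying_curve_threshold_found_numerically(self):
        damage = syn.StaticDamageParams(
            onset_kGy=5.0, amplitude=0.5, rise_scale_kGy=20.0, decay_scale_kGy=80.0
        )
        thr = damage.true_threshold(0.01)
        assert thr is not None and thr > 5.0
        assert abs(damage.curve(thr) - 1.0) == pytest.approx(0.01, abs=1e-3)


@pytest.fixture(scope="module")
def frame_fixture(tmp_path_factory):
    config = small_config(q_rings=(0.02,), pixels_per_ring=150, n_frames=20, seed=5)
    series = syn.simulate_event_dynamics(config)
    geometry = corr.DetectorGeometry(
        pixel_size_um=300.0,
        distance_m=21.2,
        wavelength_A=1.45,
        beam_center=(48.0, 48.0),
        shape=(96, 96),
    )
    frames, rings = syn.frames_from_rings(series, geometry)
    path = tmp_path_factory.mktemp("h5") / "stack.h5"
    syn.write_frames(frames, path)
    return config, series, frames, rings, path


class TestFrameIO:

    def test_round_trip_is_bit_exact(self, frame_fixture):
        config, series, frames, rings, path = frame_fixture
        back = read_frames(path)
        assert np.array_equal(back.frames, frames.frames)
        assert np.array_equal(back.timestamps, frames.timestamps)
        extracted = corr.ring_series_from_stack(back.frames, rings[0])
        n_sim = series.counts[0].shape[0]
        assert np.array_equal(extracted[:n_sim].astype(np.uint32), series.counts[0])

    def test_correlation_identical_through_file(self, frame_fixture):
        config, series, frames, rings, path = frame_fixture
        back = read_frames(path)
        n_sim = series.counts[0].shape[0]
        x = corr.ring_series_from_stack(back.frames, rings[0])[:n_sim]
        direct = corr.two_time(series.counts[0].astype(float))
        via_file = corr.two_time(x)
        assert np.array_equal(direct.values, via_file.values)

    def test_existing_file_not_overwritten(self, frame_fixture):
        *_, path = frame_fixture
        frames = frame_fixture[2]
        with pytest.raises(FileExistsError):
            syn.write_frames(frames, path)

    def test_missing_dataset_raises_named_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as fh:
            fh["entry/data/data"] = np.zeros((2, 4, 4), dtype=np.uint32)
        with pytest.raises(KeyError, match="timestamps"):
            read_frames(path)

    def test_empty_series_rejected(self):
        geometry = corr.DetectorGeometry(
            pixel_size_um=300.0,
            distance_m=21.2,
            wavelength_A=1.45,
            beam_center=(8, 8),
            shape=(16, 16),
        )
        with pytest.raises(ValueError):
            syn.FrameSeries(
                frames=np.zeros((0, 16, 16), dtype=np.uint32),
                timestamps=np.array([]),
                geometry=geometry,
            )
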