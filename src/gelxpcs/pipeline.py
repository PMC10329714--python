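"""End-to-end pipeline on synthetic presets, plus file I/O.

A run emulates one beamtime-style campaign on a gel preset: generate
speckle series over a sweep of absorber settings (fluences), correlate,
cut and fit g2 functions at a fixed starting dose, convert decay rates to
velocities, fit the fluence-velocity law to find the beam-induced-dynamics
threshold, and run the structural damage analyses.  All randomness flows
from the single run seed; deterministic stages reproduce bit-identically.

Presets
-------
soft-gel    weakly crosslinked network: intrinsic v0 = 3 nm/s, strong beam
            susceptibility alpha = 1e3 nm^3/ph (threshold Phi_D = 3e-3
            ph/s/nm^2), structural damage onset at 5 kGy (intensity rise).
strong-gel  dense network: v0 = 0.45 nm/s, alpha = 0.5 nm^3/ph (Phi_D =
            0.9 ph/s/nm^2), damage onset 20 kGy (intensity drop).
frozen      no dynamics at all; contrast stays on the baseline.
drift       pure ballistic motion at 2 nm/s, no beam response.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import correlator, dosimetry, kww, radiation, synthetic

__all__ = [
    "GelPreset",
    "PRESETS",
    "RunConfig",
    "RunReport",
    "default_beam",
    "default_sample",
    "read_frames",
    "run_pipeline",
    "write_tables",
]


@dataclass(frozen=True)
class GelPreset:
    """Ground-truth physics of a synthetic gel sample."""

    name: str
    analysis_q: float  # 1/nm, the ring used for velocities
    q_rings: tuple  # rings for the q-scaling check
    step_size_nm: float  # delta
    v0_nm_s: float  # intrinsic velocity
    alpha_nm3_ph: float  # beam susceptibility
    contrast: float = 0.1
    damage: synthetic.StaticDamageParams | None = None
    drift_speed_nm_s: float = 0.0

    def event_rate(self, fluence: float) -> float:
        """gamma(Phi) = (v0 + alpha*Phi) / delta so that Gamma/q = v0 + alpha*Phi."""
        if self.step_size_nm == 0:
            return 0.0
        return (self.v0_nm_s + self.alpha_nm3_ph * fluence) / self.step_size_nm

    def velocity(self, fluence: float) -> float:
        return self.v0_nm_s + self.alpha_nm3_ph * fluence


PRESETS = {
    "soft-gel": GelPreset(
        name="soft-gel",
        analysis_q=0.006,
        q_rings=(0.006, 0.012, 0.02),
        step_size_nm=5.0,
        v0_nm_s=3.0,
        alpha_nm3_ph=1.0e3,
        damage=synthetic.StaticDamageParams(
            onset_kGy=5.0, amplitude=0.5, rise_scale_kGy=20.0, sign=+1.0
        ),
    ),
    "strong-gel": GelPreset(
        name="strong-gel",
        analysis_q=0.02,
        q_rings=(0.02, 0.04, 0.06),
        step_size_nm=2.5,
        v0_nm_s=0.45,
        alpha_nm3_ph=0.5,
        damage=synthetic.StaticDamageParams(
            onset_kGy=20.0, amplitude=0.3, rise_scale_kGy=60.0, sign=-1.0
        ),
    ),
    "frozen": GelPreset(
        name="frozen",
        analysis_q=0.02,
        q_rings=(0.02, 0.04, 0.06),
        step_size_nm=0.0,
        v0_nm_s=0.0,
        alpha_nm3_ph=0.0,
        damage=None,
    ),
    "drift": GelPreset(
        name="drift",
        analysis_q=0.006,
        q_rings=(0.006, 0.012, 0.02),
        step_size_nm=0.0,
        v0_nm_s=2.0,
        alpha_nm3_ph=0.0,
        drift_speed_nm_s=2.0,
        damage=None,
    ),
}


def default_beam() -> dosimetry.BeamConfig:
    """The reference USAXS beam: 6e10 ph/s at 8.54 keV in 100x100 um^2."""
    return dosimetry.BeamConfig(
        flux_unattenuated=6e10,
        photon_energy_keV=8.54,
        beam_width_um=100.0,
        beam_height_um=100.0,
    )


def default_sample() -> dosimetry.SampleGeometry:
    """1.5 mm water-equivalent capillary (transmission computed, ~27.8%)."""
    return dosimetry.SampleGeometry(thickness_mm=1.5)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (schema mirrored in YAML)."""

    preset: str = "soft-gel"
    absorber_sweep: tuple = (24, 18, 16, 12, 8)
    seed: int = 0
    pixels_per_ring: int = 500
    n_frames: int = 250
    n_scatterers: int = 48
    start_dose_kGy: float = 1.0
    band_width: int = 3
    damage_criterion: float = 0.01
    mean_counts_per_pixel: float = 50.0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options: {sorted(PRESETS)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "absorber_sweep" in raw:
            raw["absorber_sweep"] = tuple(raw["absorber_sweep"])
        return cls(**raw)


@dataclass
class RunReport:
    """Serializable record of a pipeline run: provenance, tables, warnings."""

    config: dict
    dose_table: list
    per_fluence: list
    q_scaling: dict | None
    fluence_fit: dict | None
    thresholds: list
    master_curve_crossings: dict | None
    warnings: list

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), default=_jsonify, indent=2, **kwargs)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_frames(path) -> synthetic.FrameSeries:
    """Read the HDF5 stack layout back into a FrameSeries.

    Missing datasets raise KeyError naming the absent path.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        for ds in ("entry/data/data", "entry/data/timestamps", "entry/geometry"):
            if ds not in fh:
                raise KeyError(f"{path}: missing dataset or group '{ds}'")
        frames = np.asarray(fh["entry/data/data"])
        timestamps = np.asarray(fh["entry/data/timestamps"], dtype=float)
        g = fh["entry/geometry"].attrs
        geometry = correlator.DetectorGeometry(
            pixel_size_um=float(g["pixel_size_um"]),
            distance_m=float(g["distance_m"]),
            wavelength_A=float(g["wavelength_A"]),
            beam_center=tuple(g["beam_center"]),
            shape=frames.shape[1:],
        )
    return synthetic.FrameSeries(frames=frames, timestamps=timestamps, geometry=geometry)


def _scan_schedule(
    preset: GelPreset, fluence: float, dose_rate: float, start_dose: float, n_frames: int
) -> float:
    """Frame interval covering the start dose plus ~10 decay times."""
    gamma_q = max(preset.velocity(fluence) * preset.analysis_q, 1e-9)
    t2 = start_dose / max(dose_rate, 1e-12)
    total = t2 + 10.0 / gamma_q
    return total / n_frames


def _measure_velocity(config: RunConfig, preset: GelPreset, protocol, fluence: float):
    """Simulate the analysis ring at one fluence and fit the decay rate."""
    interval = _scan_schedule(
        preset, fluence, protocol.dose_rate_kGy_s, config.start_dose_kGy, config.n_frames
    )
    syn = synthetic.SyntheticConfig(
        n_scatterers=config.n_scatterers,
        event_rate=preset.event_rate(fluence),
        step_size_nm=preset.step_size_nm or 1.0,
        drift_speed_nm_s=preset.drift_speed_nm_s,
        q_rings=(preset.analysis_q,),
        pixels_per_ring=config.pixels_per_ring,
        contrast=preset.contrast,
        mean_counts_per_pixel=config.mean_counts_per_pixel,
        frame_interval_s=interval,
        n_frames=config.n_frames,
        seed=config.seed + 101 * protocol.absorber_index,
    )
    if preset.step_size_nm == 0:
        syn = replace(syn, event_rate=0.0)
    series = synthetic.simulate_event_dynamics(syn)
    ttc = correlator.two_time(
        series.counts[0],
        timestamps=series.timestamps,
        ring_q=preset.analysis_q,
        dose_rate_kGy_s=protocol.dose_rate_kGy_s,
    )
    t2 = min(
        config.start_dose_kGy / max(protocol.dose_rate_kGy_s, 1e-12),
        float(series.timestamps[-1]) * 0.5,
    )
    curve = kww.extract_g2(ttc, t2=t2, band_width=config.band_width)
    fit = kww.fit_kww(curve)
    return syn, ttc, curve, fit


def run_pipeline(config: RunConfig) -> RunReport:
    """Run simulate -> correlate -> cut/fit -> thresholds/fluence-fit.

    Stage failures are caught and recorded in the report's warnings so a
    partial run still yields its completed results.
    """
    preset = PRESETS[config.preset]
    beam = default_beam()
    sample = default_sample()
    warnings_log: list = []

    dose_df = dosimetry.dose_table(beam, sample)
    dose_rows = dose_df.to_dict(orient="records")

    per_fluence = []
    velocities = []
    for n in config.absorber_sweep:
        protocol = dosimetry.DoseProtocol(beam=beam, sample=sample, absorber_index=n)
        phi = protocol.fluence
        entry = {
            "absorber_index": n,
            "fluence_ph_s_nm2": phi,
            "dose_rate_kGy_s": protocol.dose_rate_kGy_s,
            "true_velocity_nm_s": preset.velocity(phi),
        }
        try:
            syn, ttc, curve, fit = _measure_velocity(config, preset, protocol, phi)
            entry.update(
                {
                    "frame_interval_s": syn.frame_interval_s,
                    "t2_s": curve.waiting_time,
                    "dose_label_kGy": curve.dose_label_kGy,
                    "kww_converged": fit.converged,
                    "kww_k": fit.exponent,
                    "kww_gamma_s": fit.decay_rate,
                    "kww_beta": fit.contrast,
                    "velocity_nm_s": (
                        fit.decay_rate / preset.analysis_q if fit.converged else None
                    ),
                }
            )
            if fit.converged:
                velocities.append((phi, fit.decay_rate / preset.analysis_q))
            else:
                warnings_log.append(
                    f"absorber {n}: KWW fit not converged ({fit.message})"
                )
        except Exception as exc:  # pragma: no cover - defensive stage guard
            warnings_log.append(f"absorber {n}: stage failed: {exc}")
        per_fluence.append(entry)

    # q-scaling at the highest-fluence sweep point, over the preset's rings.
    # The event rate is constant within this scan, so the cut starts at
    # t2 = 0; the frame interval resolves the fastest ring and the scan
    # length covers several decay times of the slowest one.
    q_scaling_out = None
    try:
        n_ref = config.absorber_sweep[-1]
        protocol = dosimetry.DoseProtocol(beam=beam, sample=sample, absorber_index=n_ref)
        phi_ref = protocol.fluence
        v_ref = max(preset.velocity(phi_ref), 1e-9)
        interval = 0.12 / (v_ref * max(preset.q_rings))
        n_frames_q = max(
            config.n_frames,
            int(math.ceil(8.0 / (v_ref * min(preset.q_rings)) / interval)),
        )
        syn = synthetic.SyntheticConfig(
            n_scatterers=config.n_scatterers,
            event_rate=preset.event_rate(phi_ref),
            step_size_nm=preset.step_size_nm or 1.0,
            drift_speed_nm_s=preset.drift_speed_nm_s,
            q_rings=preset.q_rings,
            pixels_per_ring=config.pixels_per_ring,
            contrast=preset.contrast,
            mean_counts_per_pixel=config.mean_counts_per_pixel,
            frame_interval_s=interval,
            n_frames=n_frames_q,
            seed=config.seed + 7,
        )
        if preset.step_size_nm == 0:
            syn = replace(syn, event_rate=0.0)
        series = synthetic.simulate_event_dynamics(syn)
        gammas = []
        for q_ring, block in zip(series.ring_q, series.counts):
            ttc = correlator.two_time(block, timestamps=series.timestamps, ring_q=q_ring)
            fit = kww.fit_kww(kww.extract_g2(ttc, t2=0.0, band_width=config.band_width))
            if fit.converged:
                gammas.append((q_ring, fit.decay_rate))
        if len(gammas) >= 3:
            qs = kww.q_scaling(gammas)
            q_scaling_out = {
                "exponent": qs.exponent,
                "prefactor": qs.prefactor,
                "velocity_nm_s": qs.velocity,
                "regime": qs.regime,
            }
        else:
            warnings_log.append("q-scaling skipped: fewer than 3 converged rings")
    except Exception as exc:  # pragma: no cover - defensive stage guard
        warnings_log.append(f"q-scaling stage failed: {exc}")

    fluence_fit_out = None
    if len(velocities) >= 3:
        resp = radiation.FluenceResponse(
            fluence=np.array([p for p, _ in velocities]),
            velocity=np.array([v for _, v in velocities]),
            group=preset.name,
            start_dose_kGy=config.start_dose_kGy,
        )
        ffit = radiation.fit_fluence_response(resp)
        fluence_fit_out = {
            "v0_nm_s": ffit.v0,
            "alpha_nm3_ph": ffit.alpha,
            "threshold_fluence_ph_s_nm2": ffit.threshold_fluence,
            "stderr_threshold": ffit.stderr_threshold,
            "converged": ffit.converged,
            "true_v0_nm_s": preset.v0_nm_s,
            "true_alpha_nm3_ph": preset.alpha_nm3_ph,
        }
    else:
        warnings_log.append("fluence fit skipped: fewer than 3 converged velocities")

    # structural damage thresholds and master curve from static intensities
    thresholds = []
    crossings = None
    if preset.damage is not None:
        intensity_by_phi, gamma_by_phi = {}, {}
        rng = np.random.default_rng(config.seed + 13)
        for n in config.absorber_sweep:
            protocol = dosimetry.DoseProtocol(beam=beam, sample=sample, absorber_index=n)
            rate = protocol.dose_rate_kGy_s
            phi = protocol.fluence
            d_max = max(5.0 * preset.damage.onset_kGy, 50.0)
            doses = np.linspace(0.0, d_max, 400)[1:]
            table = synthetic.simulate_static_intensity(
                doses, preset.damage, noise_sigma=0.002, rng=rng, dose_rate_kGy_s=rate
            )
            series = radiation.relative_intensity(
                table.q_values, table.times, table.values, dose_rate_kGy_s=rate
            )
            thr = radiation.damage_threshold(series, criterion=config.damage_criterion)
            thresholds.append(
                {
                    "absorber_index": n,
                    "dose_rate_kGy_s": rate,
                    "threshold_dose_kGy": thr.dose_kGy,
                    "true_threshold_kGy": preset.damage.true_threshold(
                        config.damage_criterion
                    ),
                }
            )
            times = table.times
            gamma_t = np.full_like(times, preset.velocity(phi) * preset.analysis_q)
            intensity_by_phi[phi] = (times, series.values)
            gamma_by_phi[phi] = (times, gamma_t)
        mc = radiation.master_curve(
            intensity_by_phi, gamma_by_phi, criterion=config.damage_criterion
        )
        crossings = {f"{phi:.4g}": x for phi, x in mc.crossings.items()}
    else:
        for n in config.absorber_sweep:
            protocol = dosimetry.DoseProtocol(beam=beam, sample=sample, absorber_index=n)
            thresholds.append(
                {
                    "absorber_index": n,
                    "dose_rate_kGy_s": protocol.dose_rate_kGy_s,
                    "threshold_dose_kGy": None,
                    "true_threshold_kGy": None,
                }
            )

    report = RunReport(
        config=asdict(config),
        dose_table=dose_rows,
        per_fluence=per_fluence,
        q_scaling=q_scaling_out,
        fluence_fit=fluence_fit_out,
        thresholds=thresholds,
        master_curve_crossings=crossings,
        warnings=warnings_log,
    )
    if config.output_dir is not None:
        write_tables(report, config.output_dir)
    return report


def write_tables(report: RunReport, outdir) -> None:
    """Persist the report: JSON summary plus CSV tables."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    pd.DataFrame(report.dose_table).to_csv(out / "dose_table.csv", index=False)
    pd.DataFrame(report.per_fluence).to_csv(out / "per_fluence.csv", index=False)
    pd.DataFrame(report.thresholds).to_csv(out / "thresholds.csv", index=False)
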