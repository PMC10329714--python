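# gelxpcs

Analysis toolkit for X-ray photon correlation spectroscopy (XPCS) studies of
**X-ray driven and intrinsic dynamics in soft viscoelastic samples** —
protein gels probed at ultra-small angles, where the beam that measures the
dynamics also drives them.

It is written for XPCS practitioners who need to (a) convert beamline
parameters into fluence, dose rate and dose, (b) reduce speckle frame series
to two-time correlation functions and Kohlrausch–Williams–Watts (KWW)
parameters, and (c) separate intrinsic sample dynamics from beam-induced
motion via fluence thresholds and damage-dose analyses.  A seeded synthetic
speckle generator with known ground truth makes every stage testable without
beamline data.

## The models at the core

**Two-time correlation** of the pixel ensemble of a q-ring,

    c²(q, t₁, t₂) = ⟨I_p(q,t₁) I_p(q,t₂)⟩_p / (⟨I_p(q,t₁)⟩_p ⟨I_p(q,t₂)⟩_p),

cut at waiting times t₂ (which carry dose labels 𝒟 = dose-rate · t₂) and
fitted with the KWW form

    g²(q, τ) = 1 + β(q) · exp(−2 (Γ(q) τ)^k).

Ballistic stress-relaxation dynamics show Γ = v·q with exponents k ≈ 1.5–2;
the velocity v = Γ/q is the q-independent observable.

**Dosimetry** (water-equivalent): with flux F behind n absorber wafers,
F = F₀·0.73ⁿ, the dose rate is 𝒟̇ = F·E·(1−T)/(V·ρ) and the accumulated
dose 𝒟 = 𝒟̇·t_exp.

**Stress-relaxation event model**: microscopic relaxation events arrive at
rate γ and displace a region by δ per event, ballistically, giving the
intermediate scattering function

    f(q,t) = Σ_N  e^{−γt} (γt)^N / N!  ·  e^{−(qNδ)²},      g² = 1 + β f².

For qδ = 0.01–0.1 this yields k between 1.5 and 2 and Γ ≈ γ·q·δ: the
observable decay rate is 10–100× slower than the event rate.

**Beam-induced dynamics**: the fluence dependence of the velocity is
v(Φ) = v₀ + αΦ; the threshold fluence Φ_D = v₀/α marks the point where
beam-driven motion overtakes the intrinsic dynamics.

## Worked example

Dose bookkeeping for the reference beam (6×10¹⁰ ph/s, 8.54 keV,
100×100 µm², 1.5 mm water-equivalent sample):

```
$ gelxpcs dose
n,flux_ph_s,fluence_ph_s_nm2,dose_rate_kGy_s
0,60000000000.0,6.0,3.9514344793813936
...
12,1374122882.7894151,0.1374122882789415,0.09049594229935087
...
24,31470228.283424877,0.003147022828342488,0.002073036827704714
```

The unattenuated beam deposits ≈ 4 kGy/s (800 kGy in a 200 s scan); twelve
25 µm Si wafers reduce that to ≈ 0.09 kGy/s.

The event model, evaluated and mapped to KWW observables:

```python
>>> from gelxpcs import EventModelParams, kww_map
>>> k, rate = kww_map(EventModelParams(event_rate=1.0, step_size=0.1, wavevector=1.0))
>>> round(k, 3), round(rate, 4), round(1.0 / rate, 1)
(1.736, 0.0948, 10.5)
```

A single event decorrelates only a fraction qδ of a speckle, so at qδ = 0.1
the correlation function decays 10.5× slower than events occur.

End-to-end synthetic campaign on the `soft-gel` preset (intrinsic velocity
v₀ = 3 nm/s, susceptibility α = 10³ nm³/ph, sweep over five absorber
settings):

```python
>>> from gelxpcs import RunConfig, run_pipeline
>>> report = run_pipeline(RunConfig(preset="soft-gel", seed=1))
>>> ff = report.fluence_fit
>>> round(ff["v0_nm_s"], 2), round(ff["alpha_nm3_ph"]), ff["threshold_fluence_ph_s_nm2"]
(3.39, 1010, 0.003354345746603751)
```

The recovered fluence threshold Φ_D ≈ 0.0034 ph s⁻¹ nm⁻² matches the
programmed v₀/α = 0.003 within the fitted uncertainty (±0.0006); the report
also carries the structural 1%-damage thresholds (≈ 5.4 kGy for this preset,
independent of dose rate) and the q-scaling check (ballistic, p ≈ 1).

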