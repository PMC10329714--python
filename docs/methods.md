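# Methods

This note records the models implemented in `gelxpcs`, the assumptions they
make, the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate about real beamline data.

## Dosimetry

The sample is treated as its water equivalent: a slab of thickness d
(default 1.5 mm, the capillary diameter) and density ρ = 1000 kg/m³,
illuminated by a beam of area A (default 100×100 µm²).  Absorbers are
stacks of n 25-µm silicon wafers, each transmitting 73% at the working
energy, so the flux and the fluence Φ = F/A scale with 0.73ⁿ.  The absorbed
dose rate is the calorimetric estimate 𝒟̇ = F·E·(1−T)/(V·ρ) with V = A·d;
flux losses in the capillary walls are neglected.  The exact relation
dose = dose-rate × time holds by construction.

Sample transmission is either supplied or computed by Beer–Lambert from a
bundled table of the mass attenuation coefficient of liquid water on the
standard 5–20 keV grid, interpolated log-log (the standard behaviour of
photon cross sections; at 8.54 keV this gives T = 27.8% for 1.5 mm).
Queries outside the grid raise rather than extrapolate.

Radiolysis rates assume the standard aqueous yield of 3 OH radicals per
100 eV absorbed.  The volumetric rate is Φ(1−T)·E·yield/d, in
radicals s⁻¹ nm⁻³; the "cube edge" (rate^(−1/3)) is the length of the cube
in which one radical appears per second.  The per-volume unit is used
consistently; with it, both the weak-gel (≈4×10⁻⁷ s⁻¹ nm⁻³, 138 nm cube)
and strong-gel (≈1.1×10⁻⁴ s⁻¹ nm⁻³, 20 nm cube) estimates are mutually
consistent, whereas a per-area unit would not reproduce either cube edge.

Absorber counts outside the set realizable by a wafer-stack absorber unit
({0, 1, 2, 4, 6, 8, 12, 16, 18, 24}) are accepted with a warning, since the
attenuation law itself is defined for any n ≥ 0.

## Stress-relaxation event model

Dynamics at ultra-small angles in gels are modeled as discrete relaxation
events: a Poisson process of rate γ, each event displacing a region by a
step δ that accumulates **ballistically** — a region that has undergone N
events has moved ∝ N, not ∝ √N, because the elastic network responds
coherently and successive relaxations of the same stress dipole act along
the same direction.  The intermediate scattering function (ISF) is the
Poisson mixture

    f(q,t) = Σ_N P(N; γt) · exp(−(qNδ)²),

evaluated with log-space Poisson weights and `logsumexp`, truncated at
N_max = ceil(γt_max + 10√(γt_max)) + 10 (Poisson tail < 10⁻¹⁰; verified
against a direct term-by-term summation oracle).

The measured correlation follows from the Siegert relation,
g² = 1 + β f².  This reading matters: fitting the KWW form
1 + β exp(−2(Γτ)^k) to 1 + f² gives Γ = γqδ exactly in the small-qδ limit
(where f → exp(−(γqδt)²), k = 2), so γ/Γ = 1/(qδ) spans 10–100 for
qδ = 0.01–0.1.  Treating the sum itself as the g² decay would instead give
Γ = γqδ/√2 and ratios up to ~140, inconsistent with the ballistic relation
Γ ≈ γqδ that the fluence analysis relies on.

`kww_map` fits over the window where the decorrelation f² lies between
0.95 and 0.05 — the full decay without the flat head and tail; the window
bounds are also the reference for the small-qδ closed-form check.  Fits
with the exponent pinned at its bounds (0.2, 4) are flagged rather than
returned as converged.

## Synthetic speckle generator

The generator realizes the event model microscopically so that generator
and analytic curve are **independent implementations of the same physics**
(cross-validated in the tests):

* Point scatterers in a box; each scatterer draws one frozen event
  displacement vector from an isotropic Gaussian with per-axis standard
  deviation √2·δ and applies it at every Poisson(γ·Δt) event.  The frozen
  direction realizes the ballistic accumulation above and reproduces
  exp(−(qNδ)²) exactly after averaging over the Gaussian.  Redrawing the
  direction per event would produce an uncorrelated random walk — a simple
  exponential ISF with Γ ∝ q², which is *not* the stress-relaxation
  phenomenology.
* Drift mode: a frozen per-scatterer velocity field, Gaussian with per-axis
  std √2·v.  A drift common to all scatterers would only translate the
  speckle phase without decorrelating the ring ensemble; the frozen random
  velocity field realizes the operational meaning of the XPCS velocity,
  Γ = v·q with k = 2.
* Diffusion mode: per-frame Gaussian steps of per-axis variance 2DΔt,
  giving Γ = D·q² and k = 1 (pure Fickian; the generator does not attempt
  the dynamically heterogeneous k < 1 of fluidized gels).
* Each ring pixel carries a random 3-D scattering vector of magnitude q
  (rings are azimuthal averages, so directions are free); the field is the
  coherent sum over scatterers, giving negative-exponential intensity
  statistics for one mode.  Partial contrast β is realized by averaging
  M = round(1/β) independent modes (Gamma-distributed intensities,
  contrast 1/M) — the standard partial-coherence model; the default
  β = 0.1 matches the ≈9.7% contrast typical of a USAXS setup at
  q = 0.02 nm⁻¹.
* Photon counting is a Poisson draw per pixel and frame with mean
  proportional to the intensity (default 50 counts/pixel).  The shot-noise
  term appears only on the TTC diagonal and in the contrast estimator,
  which subtracts 1/⟨n⟩.

Dose-dependent dynamics are simulated by modulating γ frame-by-frame with
an arbitrary response function of the accumulated dose (step responses
reproduce the block-structured TTCs of absorber-switching scans).

Structural damage fixtures are parametric relative-intensity curves: flat
at 1 up to an onset dose, then a saturating rise (or fall, for dense
networks) with optional slow decay; the noiseless 1%-crossing has a closed
form used as the detector's ground truth.  Multiplicative noise is applied
per time point, shared across q, so q-averaging does not dilute it.

**What the generator does not emulate**: detector artifacts (gaps, hot
pixels) beyond an optional mask, aging or heterogeneous dynamics (k < 1),
the radiation chemistry linking dose to the event rate (the dose response
is programmed, not derived), and the coupling of structural damage back
into the speckle dynamics.  Passing tests therefore demonstrate that the
*analysis chain* is unbiased on data obeying its assumptions, not that the
physical model is correct for any particular sample.

## Correlator

c² uses instantaneous per-frame pixel means in the denominator — exactly
the pixel-ensemble normalization, which also tolerates slow intensity
drift from damage.  Matrices are computed per ring with frames streamed in
blocks, symmetrized to remove floating-point asymmetry of the matrix
product.  Masked pixels are excluded before averaging.  A frame with zero
mean intensity in the ring is an error (division guard), not a NaN.

The contrast estimator is the normalized pixel variance minus the
shot-noise term 1/⟨n⟩, averaged over early frames (default 50) where the
sample is least damaged.  It can come out slightly negative on
contrast-free input; it is not clamped.

## KWW fitting

Cuts g²(τ) = c²(t₂+τ, t₂) start on the diagonal; a band of adjacent
diagonal-parallel rows (default 3) is averaged to reduce noise — each
sub-cut shares the lag grid and shifts t₂ by one frame, a negligible dose
difference.  Near the matrix edge the band shrinks gracefully and the
per-lag errors (∝ 1/√(n_pixels·n_rows)) grow accordingly.

Fitting is weighted least squares of 1 + β exp(−2(Γτ)^k) with initial
values from a log-log linearization; lags are down-sampled logarithmically
(≈60 points) so long flat tails do not dominate the residual.  β is free
by default and can be fixed to the measured contrast — fixing it removes
the strong β–k covariance and is what the parameter-recovery tests use.
Decay detection compares the first three lags against the tail quartile at
3 standard errors: a span-based test would trigger on pure noise for long
curves and miss decays faster than the grid head.  Flat curves return a
non-converged flag with the decay rate reported as the lower bound
resolvable from the window (1/τ_max).

Γ(q) is fitted as a power law in log-log space; |p−1| < 0.25 is classified
ballistic (velocity v = mean(Γ/q)), |p−2| < 0.25 diffusive.

## Radiation analyses

* **Damage threshold**: first dose where |I/I₀ − 1| exceeds the criterion
  (default 1%) for two consecutive points.  The two-point rule is noise
  robustness; the absolute deviation catches both rising (weak-gel) and
  falling (dense-gel) signatures.  Raising the criterion can only move the
  threshold later (monotonicity, property-tested).  No crossing is a valid
  result.
* **Fluence response**: v(Φ) = v₀ + αΦ fitted with log-space residuals,
  because velocities measured across decades of fluence carry
  multiplicative errors; linear-space is available as an option.
  Φ_D = v₀/α with first-order error propagation including the v₀–α
  covariance; α ≤ 0 flags the threshold as undefined.
* **Decay dose**: t₁′ = 1/(qv), D_decay = t₁′·𝒟̇, total = start dose +
  D_decay.  In the fully beam-driven limit v = αΦ the dose rate ∝ Φ
  cancels and D_decay plateaus — verified numerically over three decades.
* **Master curve**: the abscissa is the cumulative Σ Γᵢ·Δtᵢ rather than
  the instantaneous Γ·t, because Γ changes with accumulated dose; it
  reduces to Γ·t when Γ is constant.  The 1%-crossing abscissa per fluence
  is the "number of decorrelations to damage"; dividing by qδ converts it
  to microscopic event counts (t·γ = t·Γ/(qδ)).

## Pipeline presets

The presets encode sample classes on the scale of the experiment they
emulate: `soft-gel` (v₀ = 3 nm/s, α = 10³ nm³/ph, hence Φ_D = 3×10⁻³
ph s⁻¹ nm⁻², damage onset 5 kGy in the observed 3–9 kGy range, qδ = 0.03
at the 0.006 nm⁻¹ analysis ring) and `strong-gel` (v₀ = 0.45 nm/s,
α = 0.5 nm³/ph, Φ_D = 0.9 ph s⁻¹ nm⁻², onset 20 kGy, falling intensity,
analysis ring 0.02 nm⁻¹), plus `frozen` and `drift` for the static and
purely ballistic limits.  The event rate at fluence Φ is
γ = (v₀ + αΦ)/δ, the microscopic counterpart of the linear velocity law.

Scan schedules are chosen per fluence so that the cut at the 1 kGy
starting dose and ~10 decay times fit into the configured number of
frames; the q-scaling scan resolves its fastest ring at 0.12 decay per
frame.  Fixture sizes (500 pixels/ring, 250 frames, 48 scatterers, 10
modes) keep a five-fluence campaign around twenty seconds while leaving
the fitted Φ_D within ~20% of the programmed value; the statistical tests
use 800 pixels and 128 scatterers, where the KWW exponent recovers the
analytic model's value without noticeable bias.

## Numerical choices and degenerate inputs

* Poisson sum: log-space accumulation, truncation error < 10⁻¹⁰.
* Table comparisons against one-significant-digit published values use
  "within 10% or rounds to the printed value": at two absorber settings
  (n = 16, 18) the exact dose rate differs from the rounded printed value
  by more than 10% while rounding to it exactly.
* KWW exponent bounds (0.2, 4); hitting a bound flags non-convergence.
* q_scaling excludes non-positive rates with a warning and needs ≥3 rings.
* radical_rate at zero fluence returns rate 0 with the cube edge undefined
  (None), not an exception.
* Seeded `numpy.random.Generator` throughout; every simulation is
  bit-reproducible from its config seed, and all pipeline randomness
  derives from the single run seed.

## Known limitations

The water-equivalent dosimetry ignores element-specific absorption and
capillary losses; the event model has a single (γ, δ) rather than a
distribution (no dynamical heterogeneity, so fluidized-regime exponents
k < 1 are out of reach); the generator's dose response is prescribed
rather than emergent; and the master-curve analysis assumes the damage
mechanism is slaved to the decorrelation count, which is a hypothesis the
real experiment tests, not a law the package enforces.
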