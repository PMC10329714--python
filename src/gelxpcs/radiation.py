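"""Derived radiation-effects analyses.

Four analyses connect structure, dynamics and dose:

* **structural damage threshold** — the dose at which the q-averaged
  relative scattered intensity I/I0 deviates from 1 by more than a
  criterion (1% by default);
* **fluence response** — the linear law v(Phi) = v0 + alpha*Phi separating
  intrinsic dynamics (v0) from beam-driven dynamics (alpha*Phi), with the
  fluence threshold Phi_D = v0/alpha where the two are equal (a 100%
  beam-induced speed-up);
* **decay dose** — the dose a sample accumulates while its correlation
  function decays once (to 1 + beta*exp(-2)): D_decay = dose_rate / (q*v).
  In the fully beam-driven limit v = alpha*Phi this is independent of
  fluence, because the dose rate is itself proportional to Phi;
* **master curve** — relative intensity plotted against the accumulated
  decorrelation integral(Gamma dt): structural damage appears after a
  material-specific number of decorrelations, and dividing by q*delta
  converts that number into microscopic stress-relaxation events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "RelativeIntensitySeries",
    "DamageThreshold",
    "FluenceResponse",
    "FluenceFit",
    "DecayDoseResult",
    "MasterCurveResult",
    "relative_intensity",
    "damage_threshold",
    "fit_fluence_response",
    "decay_dose",
    "master_curve",
    "events_to_damage",
]


@dataclass
class RelativeIntensitySeries:
    """q-interval-averaged I/I0 on a dose axis (first point is 1)."""

    dose_kGy: np.ndarray
    values: np.ndarray
    q_interval: tuple
    dose_rate_kGy_s: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_kGy, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose axis must be strictly increasing")


def relative_intensity(
    q_values,
    times,
    intensity,
    q_interval: tuple = (0.006, 0.03),
    protocol=None,
    dose_rate_kGy_s: float | None = None,
) -> RelativeIntensitySeries:
    """Average I(q, t) over a q-interval and normalize to the first frame.

    ``intensity`` is [n_q, n_t].  The default interval 0.006-0.03 1/nm is
    the region of the strongest damage-induced changes and coincides with
    the q range accessible to the correlation analysis.  The dose axis is
    dose_rate * t, taken from ``protocol`` or given directly.
    """
    q = np.asarray(q_values, dtype=float)
    t = np.asarray(times, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if inten.shape != (len(q), len(t)):
        raise ValueError("intensity must be [n_q, n_t]")
    lo, hi = q_interval
    sel = (q >= lo) & (q <= hi)
    if not sel.any():
        raise ValueError(f"no q values inside the interval [{lo}, {hi}]")
    series = inten[sel].mean(axis=0)
    series = series / series[0]
    if protocol is not None:
        dose_rate_kGy_s = protocol.dose_rate_kGy_s
    if dose_rate_kGy_s is None:
        raise ValueError("provide a protocol or an explicit dose rate")
    return RelativeIntensitySeries(
        dose_kGy=t * dose_rate_kGy_s,
        values=series,
        q_interval=(lo, hi),
        dose_rate_kGy_s=dose_rate_kGy_s,
    )


@dataclass(frozen=True)
class DamageThreshold:
    """Structural damage threshold dose; ``None`` when never crossed."""

    dose_kGy: float | None
    criterion: float
    rule: str = "abs deviation > criterion for 2 consecutive points"


def damage_threshold(
    series: RelativeIntensitySeries, criterion: float = 0.01
) -> DamageThreshold:
    """First dose where |I/I0 - 1| exceeds ``criterion`` sustainably.

    The crossing must hold for two consecutive points, which makes the
    detector robust to isolated noise spikes.  Absolute deviation is used
    so both rising (soft gels) and falling (strong gels) signatures are
    caught.  Absence of a crossing is a valid result (dose is None).
    """
    if len(series.values) < 3:
        raise ValueError("need at least 3 points")
    dev = np.abs(np.asarray(series.values, dtype=float) - 1.0) > criterion
    sustained = dev[:-1] & dev[1:]
    if not sustained.any():
        return DamageThreshold(dose_kGy=None, criterion=criterion)
    i = int(np.argmax(sustained))
    return DamageThreshold(dose_kGy=float(series.dose_kGy[i]), criterion=criterion)


@dataclass
class FluenceResponse:
    """Velocity-vs-fluence data at a fixed starting dose (default 1 kGy)."""

    fluence: np.ndarray  # ph/s/nm^2
    velocity: np.ndarray  # nm/s
    group: str = ""
    start_dose_kGy: float = 1.0

    def __post_init__(self) -> None:
        f = np.asarray(self.fluence, dtype=float)
        if np.any(f < 0):
            raise ValueError("fluences must be non-negative")


@dataclass(frozen=True)
class FluenceFit:
    """Parameters of v(Phi) = v0 + alpha*Phi and the threshold Phi_D = v0/alpha."""

    v0: float
    alpha: float
    threshold_fluence: float | None
    stderr_v0: float | None = None
    stderr_alpha: float | None = None
    stderr_threshold: float | None = None
    converged: bool = True
    message: str = ""


def fit_fluence_response(
    resp: FluenceResponse, log_space: bool = True
) -> FluenceFit:
    """Fit the linear fluence-velocity law and derive the fluence threshold.

    Velocities measured across decades of fluence carry multiplicative
    errors, so the default residual is log(v_model) - log(v); set
    ``log_space=False`` for ordinary linear-space least squares.  The
    threshold Phi_D = v0/alpha marks a 100% beam-induced speed-up; it is
    undefined (flagged) when the fitted alpha vanishes.
    """
    phi = np.asarray(resp.fluence, dtype=float)
    v = np.asarray(resp.velocity, dtype=float)
    if len(phi) < 3:
        raise ValueError("need at least 3 fluence points")
    span = phi[phi > 0]
    if span.size and span.max() / span.min() < 10.0:
        warnings.warn("fluence points span less than a decade; fit may be degenerate")
    if np.any(v <= 0):
        raise ValueError("velocities must be positive")

    params = lmfit.Parameters()
    params.add("v0", value=float(np.min(v)), min=0.0)
    alpha0 = max((np.max(v) - np.min(v)) / max(np.max(phi), 1e-30), 1e-30)
    params.add("alpha", value=alpha0, min=0.0)

    def residual(p):
        model = p["v0"].value + p["alpha"].value * phi
        if log_space:
            return np.log(np.clip(model, 1e-300, None)) - np.log(v)
        return model - v

    result = lmfit.minimize(residual, params)
    v0 = float(result.params["v0"].value)
    alpha = float(result.params["alpha"].value)
    s_v0 = result.params["v0"].stderr
    s_alpha = result.params["alpha"].stderr

    if alpha <= 0:
        return FluenceFit(
            v0=v0, alpha=alpha, threshold_fluence=None,
            stderr_v0=s_v0, stderr_alpha=s_alpha,
            converged=False, message="fitted alpha <= 0; threshold undefined",
        )
    phi_d = v0 / alpha
    s_phi = None
    if s_v0 is not None and s_alpha is not None and v0 > 0:
        # first-order propagation incl. the v0-alpha covariance
        cov = 0.0
        if result.covar is not None and result.covar.shape == (2, 2):
            cov = float(result.covar[0, 1])
        rel2 = (s_v0 / v0) ** 2 + (s_alpha / alpha) ** 2 - 2.0 * cov / (v0 * alpha)
        s_phi = phi_d * np.sqrt(max(rel2, 0.0))
    return FluenceFit(
        v0=v0, alpha=alpha, threshold_fluence=phi_d,
        stderr_v0=None if s_v0 is None else float(s_v0),
        stderr_alpha=None if s_alpha is None else float(s_alpha),
        stderr_threshold=None if s_phi is None else float(s_phi),
        converged=bool(result.success),
    )


@dataclass(frozen=True)
class DecayDoseResult:
    """Decay time 1/(qv) and the dose accumulated while decaying once."""

    decay_time_s: float
    decay_dose_kGy: float
    total_threshold_dose_kGy: float


def decay_dose(
    v_nm_s: float, q_nm: float, dose_rate_kGy_s: float, start_dose_kGy: float = 1.0
) -> DecayDoseResult:
    """Dose equivalent of one correlation decay.

    t1' = 1/(q*v) is the time for g2 to fall to 1 + beta*exp(-2); the dose
    accumulated meanwhile is D_decay = t1' * dose_rate.  Adding the dose
    already received at the start of the correlation gives the total dose
    beyond which all decorrelation is beam-induced.
    """
    if v_nm_s <= 0:
        raise ValueError("velocity must be positive (no decay otherwise)")
    if q_nm <= 0:
        raise ValueError("q must be positive")
    t_decay = 1.0 / (q_nm * v_nm_s)
    d_decay = t_decay * dose_rate_kGy_s
    return DecayDoseResult(
        decay_time_s=t_decay,
        decay_dose_kGy=d_decay,
        total_threshold_dose_kGy=start_dose_kGy + d_decay,
    )


@dataclass
class MasterCurveResult:
    """Collapsed damage curves: I/I0 against the decorrelation count."""

    abscissa: dict  # fluence -> cumulative integral(Gamma dt)
    ordinate: dict  # fluence -> I/I0
    crossings: dict  # fluence -> abscissa at the 1% intensity deviation


def master_curve(
    intensity_by_fluence: dict,
    gamma_by_fluence: dict,
    criterion: float = 0.01,
) -> MasterCurveResult:
    """Rescale damage curves by the accumulated decorrelation.

    ``intensity_by_fluence`` maps fluence -> (times, I/I0); ``gamma_by_fluence``
    maps fluence -> (times, Gamma) tables (interpolated onto the intensity
    time axis when the grids differ).  The abscissa is the cumulative
    sum(Gamma_i * dt_i), the piecewise version of Gamma*t that remains valid
    when Gamma changes with accumulated dose; it reduces to Gamma*t for
    constant Gamma.  For each fluence the abscissa of the first sustained
    |I/I0 - 1| > criterion crossing is reported; curves from a common damage
    mechanism collapse, with crossings at a shared abscissa.
    """
    abscissa, ordinate, crossings = {}, {}, {}
    for phi, (t_i, rel) in intensity_by_fluence.items():
        if phi not in gamma_by_fluence:
            raise KeyError(f"no decay-rate table for fluence {phi}")
        t_g, gam = gamma_by_fluence[phi]
        t_i = np.asarray(t_i, dtype=float)
        rel = np.asarray(rel, dtype=float)
        t_g = np.asarray(t_g, dtype=float)
        gam = np.asarray(gam, dtype=float)
        if t_i[0] < t_g[0] - 1e-9 or t_i[-1] > t_g[-1] + 1e-9:
            raise ValueError(
                f"decay-rate table for fluence {phi} does not cover the "
                "intensity time axis"
            )
        g_on_t = np.interp(t_i, t_g, gam)
        x = np.concatenate(([0.0], np.cumsum(0.5 * (g_on_t[1:] + g_on_t[:-1]) * np.diff(t_i))))
        abscissa[phi] = x
        ordinate[phi] = rel
        dev = np.abs(rel - 1.0) > criterion
        sustained = dev[:-1] & dev[1:]
        crossings[phi] = float(x[int(np.argmax(sustained))]) if sustained.any() else None
    return MasterCurveResult(abscissa=abscissa, ordinate=ordinate, crossings=crossings)


def events_to_damage(crossing_abscissa: float, qdelta: float) -> float:
    """Microscopic events behind a damage crossing: t*gamma = (t*Gamma)/(q*delta).

    Uses Gamma ~ gamma*q*delta to convert the observable decorrelation count
    at the damage threshold into the number of stress-relaxation events a
    region has undergone.
    """
    if not 0.0 < qdelta < 1.0:
        raise ValueError("qdelta must be in (0, 1)")
    if crossing_abscissa < 0:
        raise ValueError("crossing abscissa must be non-negative")
    return crossing_abscissa / qdelta
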