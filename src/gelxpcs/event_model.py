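"""Poisson-Gaussian stress-relaxation event model.

Dynamics in gels at ultra-small angles are dominated by discrete stress
relaxation events.  Events occur at rate ``gamma``; a region that has
experienced ``N`` of them has moved ballistically by ``N * delta``, so the
intermediate scattering function (ISF) is a Poisson mixture

    f(q, t) = sum_N  exp(-gamma t) (gamma t)^N / N!  *  exp(-(q N delta)^2)

The measured intensity correlation follows from the Siegert relation,
g2(q,t) = 1 + beta * f(q,t)^2.  For q*delta << 1 many events are needed to
decorrelate and the sum tends to the Gaussian closed form
f = exp(-(gamma q delta t)^2): a compressed exponential with KWW exponent
k = 2 and decay rate Gamma = gamma * q * delta, i.e. the observable rate is
a factor 1/(q delta) ~ 10-100 slower than the microscopic event rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EventModelParams",
    "ModelCurve",
    "evaluate_event_model",
    "kww_map",
    "alpha_to_event_rate",
    "default_time_grid",
]


@dataclass(frozen=True)
class EventModelParams:
    """Microscopic parameters: event rate gamma (1/s), step delta (nm), q (1/nm)."""

    event_rate: float
    step_size: float
    wavevector: float

    def __post_init__(self) -> None:
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.wavevector <= 0:
            raise ValueError("wavevector must be positive")

    @property
    def qdelta(self) -> float:
        """Dimensionless single-event decorrelation parameter q*delta."""
        return self.wavevector * self.step_size


@dataclass(frozen=True)
class ModelCurve:
    """ISF values f(t) in (0, 1] on a time grid; f(0) = 1, non-increasing."""

    times: np.ndarray
    values: np.ndarray

    def g2(self, contrast: float = 1.0) -> np.ndarray:
        """Siegert relation: g2 = 1 + contrast * f^2."""
        return 1.0 + contrast * self.values**2


def _poisson_gaussian_sum(gamma_t: np.ndarray, qdelta: float) -> np.ndarray:
    """Evaluate sum_N P(N; gamma_t) exp(-(qdelta*N)^2) in log space.

    The Poisson weights are accumulated as log-probabilities and combined
    with logsumexp so the sum stays finite for large gamma*t.  Truncation at
    N_max = ceil(max + 10 sqrt(max)) + 10 keeps the neglected Poisson tail
    below 1e-10.
    """
    gamma_t = np.asarray(gamma_t, dtype=float)
    mu_max = float(np.max(gamma_t, initial=0.0))
    n_max = int(math.ceil(mu_max + 10.0 * math.sqrt(mu_max))) + 10
    n = np.arange(n_max + 1, dtype=float)

    out = np.empty_like(gamma_t)
    zero = gamma_t == 0.0
    out[zero] = 1.0  # P(0, 0) = 1, h(q, 0) = 1
    if np.any(~zero):
        mu = gamma_t[~zero][:, None]
        log_p = -mu + n[None, :] * np.log(mu) - gammaln(n[None, :] + 1.0)
        log_h = -((qdelta * n) ** 2)[None, :]
        out[~zero] = np.exp(logsumexp(log_p + log_h, axis=1))
    return out


def evaluate_event_model(params: EventModelParams, times) -> ModelCurve:
    """Forward-evaluate the Poisson-Gaussian ISF on ``times`` (seconds)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    values = _poisson_gaussian_sum(params.event_rate * t, params.qdelta)
    return ModelCurve(times=t, values=values)


def default_time_grid(params: EventModelParams, n_points: int = 200) -> np.ndarray:
    """Log-spaced grid spanning 1e-2 to 1e2 times the expected decay time.

    The expected KWW decay time is 1/(gamma q delta); four decades around it
    resolve both the flat head and the decayed tail of the curve.
    """
    t_decay = 1.0 / (params.event_rate * params.qdelta)
    return np.logspace(math.log10(t_decay) - 2.0, math.log10(t_decay) + 2.0, n_points)


def kww_map(params: EventModelParams, fitter=None) -> tuple[float, float]:
    """Map (gamma, delta, q) to the observable KWW pair (k, Gamma).

    Evaluates the model ISF, forms g2 = 1 + f^2 (unit contrast), and fits
    the KWW form 1 + exp(-2 (Gamma tau)^k) over the decay window where the
    decorrelation f^2 lies between 0.95 and 0.05.  ``fitter`` may override
    the fitting routine; the default is :func:`gelxpcs.kww.fit_kww`.

    Returns (k, Gamma); raises ``RuntimeError`` if the fit does not converge.
    """
    if not 0.0 < params.qdelta < 1.0:
        raise ValueError("kww_map expects q*delta in (0, 1)")
    times = default_time_grid(params)
    curve = evaluate_event_model(params, times)
    decorrelation = curve.values**2
    window = (decorrelation <= 0.95) & (decorrelation >= 0.05)
    if window.sum() < 8:
        raise RuntimeError("decay window too narrow to fit")

    tau = times[window]
    g2 = 1.0 + decorrelation[window]

    if fitter is None:
        from .kww import G2Curve, fit_kww

        g2curve = G2Curve(lag_times=tau, g2=g2, ring_q=params.wavevector)
        fit = fit_kww(g2curve, fix_contrast=1.0)
        if not fit.converged:
            raise RuntimeError("KWW fit of the event-model curve did not converge")
        return fit.exponent, fit.decay_rate
    return fitter(tau, g2)


def alpha_to_event_rate(alpha: float, fluence: float, step: float) -> float:
    """Microscopic event rate driven by the beam: gamma = alpha * fluence / delta.

    ``alpha`` (nm^3/ph) is the material susceptibility of the fluence-velocity
    law v = v0 + alpha * fluence; dividing the induced velocity by the step
    size converts it to an event rate.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if alpha < 0 or fluence < 0:
        raise ValueError("alpha and fluence must be non-negative")
    return alpha * fluence / step
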