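"""Kohlrausch-Williams-Watts analysis of two-time correlation matrices.

Workflow: cut one-time correlation functions g2(tau) out of a TTC at chosen
waiting times t2 (which carry dose labels, dose = dose_rate * t2), fit each
cut with the KWW form

    g2(tau) = 1 + beta * exp(-2 (Gamma tau)^k)

and summarize the q-dependence of the decay rates as a power law
Gamma = c * q^p.  p ~ 1 is ballistic stress-relaxation motion with velocity
v = Gamma/q; p ~ 2 is diffusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .correlator import TwoTimeMatrix

__all__ = [
    "G2Curve",
    "KWWFit",
    "QScalingFit",
    "extract_g2",
    "fit_kww",
    "q_scaling",
    "dose_label",
]


@dataclass
class G2Curve:
    """One-time correlation cut: g2 values on a lag grid, with metadata."""

    lag_times: np.ndarray
    g2: np.ndarray
    std_errors: np.ndarray | None = None
    waiting_time: float = 0.0
    dose_label_kGy: float | None = None
    ring_q: float = np.nan

    def __post_init__(self) -> None:
        tau = np.asarray(self.lag_times, dtype=float)
        if np.any(tau < 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("lag times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(np.asarray(self.g2, dtype=float))):
            raise ValueError("g2 values must be finite")


@dataclass(frozen=True)
class KWWFit:
    """Result of a KWW fit: contrast, decay rate (1/s), exponent, errors."""

    contrast: float
    decay_rate: float
    exponent: float
    stderr_contrast: float | None
    stderr_decay_rate: float | None
    stderr_exponent: float | None
    converged: bool
    message: str = ""
    fit_window: tuple = (0.0, np.inf)


def extract_g2(
    ttc: TwoTimeMatrix,
    t2: float,
    max_lag: float | None = None,
    band_width: int = 3,
    dose_rate_kGy_s: float | None = None,
) -> G2Curve:
    """Horizontal cut of the TTC starting on the diagonal at waiting time t2.

    g2(tau) = c2(t2 + tau, t2) with tau = t1 - t2 >= 0.  To reduce noise the
    cut is averaged over ``band_width`` adjacent diagonal-parallel rows
    (each sub-cut starts one frame later but shares the same lag grid); the
    symmetrized matrix makes the direction of the cut immaterial.  The dose
    label is dose_rate * t2.
    """
    times = np.asarray(ttc.timestamps, dtype=float)
    n = len(times)
    if not times[0] <= t2 <= times[-1]:
        raise ValueError(f"t2={t2} outside the matrix time range")
    j0 = int(np.argmin(np.abs(times - t2)))
    if max_lag is None:
        max_lag = times[-1] - times[j0]
    if times[j0] + max_lag > times[-1] + 1e-12:
        raise ValueError("t2 + max_lag beyond the matrix time range")

    n_lags = int(np.searchsorted(times - times[j0], max_lag, side="right"))
    n_lags = min(n_lags, n - j0)
    band = max(1, int(band_width))

    c2 = np.asarray(ttc.values, dtype=float)
    samples = np.full((band, n_lags), np.nan)
    for b in range(band):
        r = j0 + b
        m = min(n_lags, n - r)
        if m <= 0:
            break
        samples[b, :m] = c2[r, r : r + m]
    n_rows = np.sum(~np.isnan(samples), axis=0)
    cut = np.nanmean(samples, axis=0)

    # statistical error from the pixel-ensemble size; band rows are nearly
    # independent speckle realizations at short lags
    sigma = 1.0 / np.sqrt(max(ttc.n_pixels, 1) * n_rows)

    rate = dose_rate_kGy_s if dose_rate_kGy_s is not None else ttc.dose_rate_kGy_s
    return G2Curve(
        lag_times=times[j0 : j0 + n_lags] - times[j0],
        g2=cut,
        std_errors=sigma,
        waiting_time=times[j0],
        dose_label_kGy=None if rate is None else rate * times[j0],
        ring_q=ttc.ring_q,
    )


def _log_downsample(tau: np.ndarray, n_target: int = 60) -> np.ndarray:
    """Indices of ~n_target log-spaced lags (always keeps first and last)."""
    positive = np.flatnonzero(tau > 0)
    if positive.size <= n_target:
        return np.arange(len(tau))
    grid = np.geomspace(tau[positive[0]], tau[-1], n_target)
    idx = np.unique(np.searchsorted(tau, grid))
    idx = np.clip(idx, 0, len(tau) - 1)
    keep = np.unique(np.concatenate(([0], idx, [len(tau) - 1])))
    return keep


def _initial_guess(tau, y_norm):
    """KWW start values by linearizing ln(-ln y / 2) against ln tau."""
    ok = (y_norm > 0.01) & (y_norm < 0.99) & (tau > 0)
    if ok.sum() >= 3:
        z = np.log(-np.log(y_norm[ok]) / 2.0)
        slope, intercept = np.polyfit(np.log(tau[ok]), z, 1)
        k0 = float(np.clip(slope, 0.3, 3.5))
        gamma0 = float(np.exp(intercept / k0))
    else:
        k0, gamma0 = 1.0, 1.0 / max(tau[-1], 1e-12)
    return gamma0, k0


def fit_kww(
    curve: G2Curve,
    fix_contrast: float | None = None,
    log_downsample: bool = True,
    k_bounds: tuple = (0.2, 4.0),
) -> KWWFit:
    """Weighted least-squares fit of 1 + beta exp(-2 (Gamma tau)^k).

    Initial values come from a log-log linearization of the decay.  Lags are
    down-sampled logarithmically before fitting so long flat tails do not
    dominate the residual.  A curve with no decay inside the window, or a
    fitted k pinned outside ``k_bounds``, is flagged as non-converged; for a
    flat curve the reported decay rate is the lower bound resolvable from
    the lag window (1 / max lag).
    """
    tau = np.asarray(curve.lag_times, dtype=float)
    g2 = np.asarray(curve.g2, dtype=float)
    sigma = (
        np.ones_like(g2)
        if curve.std_errors is None
        else np.asarray(curve.std_errors, dtype=float)
    )
    keep = tau > 0
    tau, g2, sigma = tau[keep], g2[keep], sigma[keep]
    if log_downsample:
        idx = _log_downsample(tau)
        tau, g2, sigma = tau[idx], g2[idx], sigma[idx]
    if len(tau) < 8:
        raise ValueError("need at least 8 positive-lag points spanning the decay")

    beta0 = fix_contrast if fix_contrast is not None else max(np.max(g2) - 1.0, 1e-3)
    # decay detection: the first lags must sit significantly above the tail
    # (a span or quartile test would miss decays faster than the grid head)
    n_head = 3
    n_tail = max(len(g2) // 4, 3)
    drop = float(g2[:n_head].mean() - g2[-n_tail:].mean())
    if curve.std_errors is None:
        flat = drop < 0.02 * beta0
    else:
        se = float(np.median(sigma)) * math.sqrt(1.0 / n_head + 1.0 / n_tail)
        flat = drop < max(3.0 * se, 0.02 * beta0)
    if flat:
        return KWWFit(
            contrast=beta0,
            decay_rate=1.0 / tau[-1],
            exponent=np.nan,
            stderr_contrast=None,
            stderr_decay_rate=None,
            stderr_exponent=None,
            converged=False,
            message="no decay within the lag window; decay rate is a lower bound",
            fit_window=(tau[0], tau[-1]),
        )

    gamma0, k0 = _initial_guess(tau, np.clip((g2 - 1.0) / beta0, 1e-9, None))

    model = lmfit.Model(
        lambda tau, beta, gamma, k: 1.0 + beta * np.exp(-2.0 * (gamma * tau) ** k)
    )
    params = model.make_params()
    params["beta"].set(value=beta0, min=1e-6, max=1.2, vary=fix_contrast is None)
    params["gamma"].set(value=max(gamma0, 1e-12), min=1e-15)
    params["k"].set(value=k0, min=k_bounds[0], max=k_bounds[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(g2, params, tau=tau, weights=1.0 / sigma)

    k_fit = float(result.params["k"].value)
    at_bound = k_fit <= k_bounds[0] * 1.001 or k_fit >= k_bounds[1] * 0.999
    converged = bool(result.success) and not at_bound

    def _err(name):
        e = result.params[name].stderr
        return None if e is None else float(e)

    return KWWFit(
        contrast=float(result.params["beta"].value),
        decay_rate=float(result.params["gamma"].value),
        exponent=k_fit,
        stderr_contrast=_err("beta"),
        stderr_decay_rate=_err("gamma"),
        stderr_exponent=_err("k"),
        converged=converged,
        message="" if converged else "fit hit exponent bounds or failed",
        fit_window=(tau[0], tau[-1]),
    )


@dataclass(frozen=True)
class QScalingFit:
    """Power law Gamma = prefactor * q^p and, if ballistic, v = Gamma/q."""

    exponent: float
    prefactor: float
    velocity: float | None  # nm/s, defined when the scaling is ~linear
    regime: str  # "ballistic", "diffusive", or "other"


def q_scaling(fits) -> QScalingFit:
    """Fit Gamma(q) = c * q^p in log-log space over a set of rings.

    ``fits`` is an iterable of (q, Gamma).  Non-positive rates are excluded
    with a warning.  |p - 1| < 0.25 is reported as ballistic with the
    velocity v = mean(Gamma/q); |p - 2| < 0.25 as diffusive.
    """
    pairs = [(float(q), float(g)) for q, g in fits]
    good = [(q, g) for q, g in pairs if g > 0 and q > 0]
    if len(good) < len(pairs):
        warnings.warn(f"excluded {len(pairs) - len(good)} non-positive decay rates")
    if len(good) < 3:
        raise ValueError("need at least 3 rings with positive decay rates")
    q = np.array([p[0] for p in good])
    gamma = np.array([p[1] for p in good])
    p, logc = np.polyfit(np.log(q), np.log(gamma), 1)
    velocity = None
    regime = "other"
    if abs(p - 1.0) < 0.25:
        regime = "ballistic"
        velocity = float(np.mean(gamma / q))
    elif abs(p - 2.0) < 0.25:
        regime = "diffusive"
    return QScalingFit(
        exponent=float(p), prefactor=float(np.exp(logc)), velocity=velocity,
        regime=regime,
    )


def dose_label(t2: float, protocol) -> float:
    """Dose accumulated at waiting time t2, in kGy (dose_rate * t2).

    This labels the start of the correlation cut; the sample keeps accruing
    dose along the lag axis, so the label is the dose at tau = 0, not over
    the whole cut.
    """
    if t2 < 0:
        raise ValueError("t2 must be non-negative")
    return protocol.dose_rate_kGy_s * t2
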