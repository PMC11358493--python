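"""Macro-to-micro dosimetry from biodistribution time series.

Organ-level gamma-counting measurements over days post-injection define
a time-dose-rate curve (TRC) per tissue and chain component.  The TRC
is fit with a bi-exponential, integrated analytically to six parent
half-lives for the total absorbed dose D, and converted into
extrapolation factors c_t = D / dose_rate(t) that scale a single
dose-rate autoradiograph at time t into a map of total absorbed dose.
Uncertainty bands come from modulating the fitted parameters by one
standard deviation.

Times are hours post-injection; dose rates mGy/h unless stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .chain_kinetics import AC225_CHAIN, SECONDS_PER_HOUR
from .dar_dosimetry import DoseRateVolume

__all__ = [
    "TimeDoseRatePoint",
    "BiexpFit",
    "ExtrapolationFactors",
    "DoseVolume",
    "DEFAULT_HORIZON_H",
    "fit_biexponential",
    "integrate_trc",
    "extrapolation_factor",
    "scale_dose_map",
    "combine_components",
]

#: Default integration horizon: six 225Ac half-lives, in hours (~59.4 d).
DEFAULT_HORIZON_H = 6.0 * AC225_CHAIN.parent.half_life / SECONDS_PER_HOUR


@dataclass(frozen=True)
class TimeDoseRatePoint:
    """One biodistribution measurement of a tissue's mean dose rate."""

    time: float  # h post-injection
    dose_rate: float  # mGy/h
    subject_id: str = ""
    component: str = "Ac225"  # "Ac225" or "free_Bi213"

    def __post_init__(self) -> None:
        if self.time < 0 or self.dose_rate < 0:
            raise ValueError("time and dose_rate must be >= 0")


@dataclass
class BiexpFit:
    """Bi-exponential dose-rate model A1 e^{-mu1 t} + A2 e^{-mu2 t}.

    ``bound_upper``/``bound_lower`` are the +-1 sigma parameter sets
    (amplitudes up with rates down, and vice versa) whose curves bracket
    the central fit at all times.
    """

    amplitudes: tuple[float, float]  # mGy/h
    rates: tuple[float, float]  # 1/h, both > 0
    covariance: np.ndarray  # 4x4 in order (A1, mu1, A2, mu2)
    bound_upper: tuple[float, float, float, float]
    bound_lower: tuple[float, float, float, float]

    def rate(self, t: float | np.ndarray, params=None) -> float | np.ndarray:
        """Model dose rate at time t (h); optionally for a bound set."""
        if params is None:
            a1, a2 = self.amplitudes
            m1, m2 = self.rates
        else:
            a1, m1, a2, m2 = params
        t = np.asarray(t, dtype=float)
        out = a1 * np.exp(-m1 * t) + a2 * np.exp(-m2 * t)
        return float(out) if out.ndim == 0 else out

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.amplitudes[0], self.rates[0], self.amplitudes[1], self.rates[1])


def _biexp(t, a1, m1, a2, m2):
    return a1 * np.exp(-m1 * t) + a2 * np.exp(-m2 * t)


def fit_biexponential(points: list[TimeDoseRatePoint]) -> BiexpFit:
    """Non-negative-amplitude least-squares bi-exponential fit.

    Initialization peels the slow component off the late-time tail in
    log space and assigns the residual to the fast component.  A
    mono-exponential truth collapses cleanly (A2 -> 0).  Requires at
    least 4 distinct time points.
    """
    t = np.array([p.time for p in points], dtype=float)
    y = np.array([p.dose_rate for p in points], dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points for 4 parameters")

    order = np.argsort(t)
    t, y = t[order], y[order]

    # tail log-linear fit for the slow component
    n_tail = max(2, t.size // 2)
    tt, yy = t[-n_tail:], np.maximum(y[-n_tail:], 1e-300)
    slope, intercept = np.polyfit(tt, np.log(yy), 1)
    m2_0 = max(-slope, 1e-6)
    a2_0 = math.exp(intercept)
    resid = np.maximum(y - a2_0 * np.exp(-m2_0 * t), 0.0)
    a1_0 = max(float(resid[0]), 1e-3 * max(y.max(), 1e-300))
    m1_0 = max(10.0 * m2_0, 1e-4)
    p0 = [a1_0, m1_0, a2_0, m2_0]

    try:
        popt, pcov = curve_fit(
            _biexp, t, y, p0=p0,
            bounds=([0.0, 1e-12, 0.0, 1e-12], [np.inf] * 4),
            maxfev=50000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"bi-exponential fit did not converge: {exc}") from exc

    a1, m1, a2, m2 = popt
    if m1 < m2:  # order components fast-first
        a1, m1, a2, m2 = a2, m2, a1, m1
        perm = [2, 3, 0, 1]
        pcov = pcov[np.ix_(perm, perm)]
    sig = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    sig = np.where(np.isfinite(sig), sig, 0.0)
    upper = (a1 + sig[0], max(m1 - sig[1], 1e-12), a2 + sig[2], max(m2 - sig[3], 1e-12))
    lower = (max(a1 - sig[0], 0.0), m1 + sig[1], max(a2 - sig[2], 0.0), m2 + sig[3])
    return BiexpFit(
        amplitudes=(float(a1), float(a2)),
        rates=(float(m1), float(m2)),
        covariance=pcov,
        bound_upper=tuple(float(v) for v in upper),
        bound_lower=tuple(float(v) for v in lower),
    )


def integrate_trc(
    fit: BiexpFit, horizon: float = DEFAULT_HORIZON_H, params=None
) -> float:
    """Total absorbed dose: analytic TRC integral to ``horizon`` hours.

        D = sum_i A_i / mu_i (1 - e^{-mu_i * horizon})   [mGy]
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if params is None:
        params = fit.params
    a1, m1, a2, m2 = params
    if m1 <= 0 or m2 <= 0:
        raise ValueError("rates must be > 0")
    return a1 / m1 * (-math.expm1(-m1 * horizon)) + a2 / m2 * (-math.expm1(-m2 * horizon))


@dataclass
class ExtrapolationFactors:
    """Dose-per-dose-rate scaling factors c_t = D / dose_rate(t).

    ``c_values`` maps a reference time (h) to the central factor in
    mGy per (mGy/h); ``bounds`` gives the (lower, upper) factors from
    the +-1 sigma bound curves.  total_dose is the central D in mGy.
    """

    total_dose: float
    c_values: dict[float, float]
    bounds: dict[float, tuple[float, float]]


def extrapolation_factor(
    fit: BiexpFit, t_ref: float, horizon: float = DEFAULT_HORIZON_H
) -> ExtrapolationFactors:
    """Extrapolation factor at one reference time, with bound estimates."""
    rate = fit.rate(t_ref)
    if rate <= 0:
        raise ValueError(f"fitted dose rate at t={t_ref} h is not positive")
    dose = integrate_trc(fit, horizon)
    c = dose / rate
    candidates = [c]
    for params in (fit.bound_upper, fit.bound_lower):
        r_b = fit.rate(t_ref, params)
        if r_b > 0:
            candidates.append(integrate_trc(fit, horizon, params) / r_b)
    return ExtrapolationFactors(
        total_dose=dose,
        c_values={t_ref: c},
        bounds={t_ref: (min(candidates), max(candidates))},
    )


@dataclass
class DoseVolume:
    """Total absorbed dose per voxel (Gy) with optional bound maps."""

    dose: np.ndarray  # [z, y, x], Gy
    voxel_dims: tuple[float, float, float]
    dose_lower: np.ndarray | None = None
    dose_upper: np.ndarray | None = None


def scale_dose_map(
    rate_map: DoseRateVolume, c: ExtrapolationFactors, t_ref: float
) -> DoseVolume:
    """Scale a dose-rate snapshot into total absorbed dose.

    Voxelwise dose = dose_rate * c_{t_ref}; the (lower, upper) factor
    bounds propagate into bound maps.  Units carry through: Gy/h times
    h gives Gy.
    """
    factor = c.c_values[t_ref]
    lo, hi = c.bounds[t_ref]
    if factor < 0 or lo < 0:
        raise ValueError("extrapolation factors must be non-negative")
    return DoseVolume(
        dose=rate_map.dose_rate * factor,
        voxel_dims=rate_map.voxel_dims,
        dose_lower=rate_map.dose_rate * lo,
        dose_upper=rate_map.dose_rate * hi,
    )


def combine_components(
    dose_ac: float, bi_to_ac_dose_ratio: float
) -> tuple[float, float]:
    """Add the free-213Bi contribution to an organ-mean 225Ac dose.

    The free-213Bi dose is only known at organ level (its spatial
    distribution decays away before imaging), so the combination is a
    scalar addition: total = dose_ac * (1 + ratio), and the bismuth
    fraction of the total is ratio / (1 + ratio).
    """
    if bi_to_ac_dose_ratio < 0:
        raise ValueError("dose ratio must be >= 0")
    total = dose_ac * (1.0 + bi_to_ac_dose_ratio)
    fraction_bi = bi_to_ac_dose_ratio / (1.0 + bi_to_ac_dose_ratio)
    return total, fraction_bi
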