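"""Gamma-counter energy-window quantification.

Organ and tumor activities are measured in a NaI(Tl) gamma counter via
the 218 keV line of 221Fr (window 168-268 keV) and the 440 keV line of
213Bi (window 370-510 keV).  Each window is fit with a Gaussian peak on
a linear background to remove ambient background and down-scatter, then
converted to activity with branching ratio, detector efficiency and
live time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EnergySpectrum",
    "WindowFit",
    "FitError",
    "fit_window",
    "counts_to_activity",
    "calibrate_efficiency",
    "FR221_WINDOW_KEV",
    "BI213_WINDOW_KEV",
    "FR221_CAL_WINDOW_KEV",
    "BI213_CAL_WINDOW_KEV",
]

# Default analysis windows, and the windows used for droplet calibration.
FR221_WINDOW_KEV = (168.0, 268.0)
BI213_WINDOW_KEV = (370.0, 510.0)
FR221_CAL_WINDOW_KEV = (175.0, 250.0)
BI213_CAL_WINDOW_KEV = (385.0, 490.0)


class FitError(RuntimeError):
    """Raised when a window fit fails to converge; carries residuals."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class EnergySpectrum:
    """Histogram of counts vs energy with the counter's live time."""

    bin_edges: np.ndarray  # keV, length n_bins + 1, strictly increasing
    counts: np.ndarray  # length n_bins, >= 0
    live_time: float  # s

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.shape != (self.bin_edges.size - 1,):
            raise ValueError("counts length must be len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.live_time <= 0:
            raise ValueError("live_time must be > 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class WindowFit:
    """Result of a Gaussian-plus-linear fit in one energy window.

    ``net_counts`` is the fitted Gaussian area (clamped at zero with
    ``clamped=True`` if the fit went negative); ``background_counts``
    is the window total minus the net, so the two always sum to the
    window total.
    """

    net_counts: float
    background_counts: float
    gaussian_params: tuple[float, float, float]  # center keV, sigma keV, area counts
    linear_params: tuple[float, float]  # slope counts/keV/bin-width, intercept
    uncertainty: float  # 1 sigma on net_counts
    clamped: bool = False


def _model(x: np.ndarray, area: float, center: float, sigma: float,
           slope: float, intercept: float, bin_width: float) -> np.ndarray:
    gauss = (
        area
        * bin_width
        / (math.sqrt(2.0 * math.pi) * sigma)
        * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    )
    return gauss + slope * x + intercept


def fit_window(spectrum: EnergySpectrum, window: tuple[float, float]) -> WindowFit:
    """Fit a Gaussian photopeak on a linear background inside ``window``.

    Initialization: center at the window midpoint, width at one sixth of
    the window, area from the window total minus a linear interpolation
    between the endpoint bins.  Net counts are never negative; a negative
    fitted area is clamped to zero and flagged.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be (lo, hi) with lo < hi")
    if lo < spectrum.bin_edges[0] or hi > spectrum.bin_edges[-1]:
        raise ValueError("window must lie within the spectrum support")
    centers = spectrum.bin_centers
    sel = (centers >= lo) & (centers <= hi)
    if np.count_nonzero(sel) < 6:
        raise ValueError("need at least 6 bins inside the window")
    x = centers[sel]
    y = spectrum.counts[sel]
    bin_width = float(np.mean(np.diff(spectrum.bin_edges)))

    # endpoint-based linear background estimate for initialization
    b0, b1 = y[0], y[-1]
    slope0 = (b1 - b0) / (x[-1] - x[0])
    intercept0 = b0 - slope0 * x[0]
    area0 = max(float(np.sum(y - (slope0 * x + intercept0))), 1.0)
    p0 = [area0, 0.5 * (lo + hi), (hi - lo) / 6.0, slope0, intercept0]

    def f(xx, area, center, sigma, slope, intercept):
        return _model(xx, area, center, sigma, slope, intercept, bin_width)

    try:
        popt, pcov = curve_fit(
            f, x, y, p0=p0,
            bounds=([-np.inf, lo, bin_width / 2.0, -np.inf, -np.inf],
                    [np.inf, hi, (hi - lo), np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = y - f(x, *p0)
        raise FitError(f"window fit did not converge: {exc}", resid) from exc

    area, center, sigma, slope, intercept = popt
    sigma_area = float(np.sqrt(max(pcov[0, 0], 0.0))) if np.all(np.isfinite(pcov)) else float("nan")
    clamped = area < 0
    net = max(float(area), 0.0)
    total = float(np.sum(y))
    return WindowFit(
        net_counts=net,
        background_counts=total - net,
        gaussian_params=(float(center), float(sigma), net),
        linear_params=(float(slope), float(intercept)),
        uncertainty=sigma_area,
        clamped=clamped,
    )


def counts_to_activity(
    net: float, branching: float, efficiency: float, live_time: float
) -> tuple[float, float]:
    """Convert net window counts to activity in Bq.

    activity = net / (branching * efficiency * live_time), with the
    Poisson 1-sigma on ``net`` propagated.  Returns ``(activity, sigma)``.
    """
    if not 0.0 < branching <= 1.0 or not 0.0 < efficiency <= 1.0:
        raise ValueError("branching and efficiency must be in (0, 1]")
    if live_time <= 0:
        raise ValueError("live_time must be > 0")
    if net < 0:
        raise ValueError("net counts must be >= 0")
    denom = branching * efficiency * live_time
    return net / denom, math.sqrt(net) / denom


def calibrate_efficiency(
    known_activities: np.ndarray,
    measured_nets: np.ndarray,
    branching: float,
    live_time: float,
) -> tuple[float, float]:
    """Detector efficiency from a known-activity calibration series.

    Fits the proportionality net = eff * branching * live_time * A by
    least squares through the origin.  Returns ``(efficiency, sigma)``.
    """
    A = np.asarray(known_activities, dtype=float)
    m = np.asarray(measured_nets, dtype=float)
    if A.shape != m.shape or A.size < 1:
        raise ValueError("need equal-length, non-empty activity/net lists")
    if np.all(A == 0):
        raise ValueError("degenerate design: all calibration activities are zero")
    if not 0.0 < branching <= 1.0 or live_time <= 0:
        raise ValueError("branching in (0, 1] and live_time > 0 required")
    rate = m / (branching * live_time)  # implied eff * A
    denom = float(np.sum(A * A))
    eff = float(np.sum(A * rate) / denom)
    if A.size > 1:
        resid = rate - eff * A
        dof = A.size - 1
        sigma = math.sqrt(float(np.sum(resid**2)) / dof / denom)
    else:
        # single pair: Poisson error on the one net count
        sigma = math.sqrt(max(m[0], 0.0)) / (branching * live_time * A[0])
    return eff, sigma
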