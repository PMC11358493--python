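"""Decay-chain kinetics for the 225Ac alpha chain.

225Ac (t1/2 = 9.9 d) decays through 221Fr (4.8 min), 217At (32 ms),
213Bi (45.6 min) and 213Po (3.72 us), emitting four alpha particles per
chain decay.  The short-lived progeny 221Fr and 217At follow the parent
within minutes, but 213Bi is slow enough that nuclear recoil can decouple
it from the parent's location ("free" 213Bi, which accumulates notably in
kidneys).  This module provides the two-nuclide parent/daughter activity
relations used to quantify that excess from time-resolved gamma counting,
plus the detector frame-coincidence correction needed when a progeny
half-life (217At) is on the order of the camera frame period.

All internal time quantities are seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Nuclide",
    "DecayChain",
    "RatioSeries",
    "AC225_CHAIN",
    "SECONDS_PER_DAY",
    "SECONDS_PER_HOUR",
    "ratio_at_time",
    "initial_daughter_activity",
    "fit_initial_ratio",
    "free_daughter_excess",
    "frame_coincidence_factor",
    "simulate_frame_coincidence",
    "decay_correct",
    "parse_duration",
]

SECONDS_PER_DAY = 86_400.0
SECONDS_PER_HOUR = 3_600.0

_UNIT_SECONDS = {
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "min": 60.0,
    "h": SECONDS_PER_HOUR,
    "d": SECONDS_PER_DAY,
}


def parse_duration(text: str | float) -> float:
    """Parse a duration with an explicit unit suffix into seconds.

    Accepts e.g. ``"9.9 d"``, ``"45.6 min"``, ``"32 ms"``, ``"24 h"``.
    Bare numbers are taken as seconds already.
    """
    if isinstance(text, (int, float)):
        return float(text)
    parts = text.strip().split()
    if len(parts) != 2 or parts[1] not in _UNIT_SECONDS:
        raise ValueError(
            f"duration {text!r} must be '<number> <unit>' with unit in "
            f"{sorted(_UNIT_SECONDS)}"
        )
    return float(parts[0]) * _UNIT_SECONDS[parts[1]]


@dataclass(frozen=True)
class Nuclide:
    """A member of the decay chain.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"Ac-225"``.
    half_life : float
        Physical half-life in seconds; must be positive.
    alpha_energy : float
        Mean alpha energy in MeV (0 for pure beta emitters).
    alpha_yield : float
        Alpha emissions of this nuclide per parent chain decay.  For the
        225Ac chain the yields are 1, 1, 1, 0.021 and 0.979 for Ac, Fr,
        At, Bi and Po respectively (the 213Bi alpha branch is 2.1%).
    """

    name: str
    half_life: float
    alpha_energy: float = 0.0
    alpha_yield: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError(f"{self.name}: half_life must be > 0")
        if not 0.0 <= self.alpha_yield <= 1.0:
            raise ValueError(f"{self.name}: alpha_yield must be in [0, 1]")
        if self.alpha_energy < 0:
            raise ValueError(f"{self.name}: alpha_energy must be >= 0")

    @property
    def lam(self) -> float:
        """Decay constant lambda = ln 2 / half_life, in 1/s."""
        return math.log(2.0) / self.half_life


@dataclass(frozen=True)
class DecayChain:
    """Ordered decay chain with a designated parent and monitored daughter.

    The parent must have the longest half-life in the chain.  The
    monitored daughter is the nuclide whose activity ratio to the parent
    is tracked by gamma counting (213Bi for the 225Ac chain).
    """

    nuclides: tuple[Nuclide, ...]
    monitored_daughter: str = "Bi-213"
    yield_tolerance: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclides", tuple(self.nuclides))
        if not self.nuclides:
            raise ValueError("chain must contain at least one nuclide")
        parent = self.nuclides[0]
        if any(n.half_life > parent.half_life for n in self.nuclides):
            raise ValueError("parent (first nuclide) must have the longest half-life")
        total = self.alphas_per_chain
        if abs(total - round(total)) > self.yield_tolerance:
            raise ValueError(
                f"alpha yields per chain decay sum to {total:.3f}, "
                "not within tolerance of an integer"
            )

    @property
    def parent(self) -> Nuclide:
        return self.nuclides[0]

    @property
    def daughter(self) -> Nuclide:
        for n in self.nuclides:
            if n.name == self.monitored_daughter:
                return n
        raise KeyError(f"monitored daughter {self.monitored_daughter!r} not in chain")

    def __getitem__(self, name: str) -> Nuclide:
        for n in self.nuclides:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def alphas_per_chain(self) -> float:
        return sum(n.alpha_yield for n in self.nuclides)

    @property
    def lam_parent(self) -> float:
        return self.parent.lam

    @property
    def lam_daughter(self) -> float:
        return self.daughter.lam

    @property
    def equilibrium_ratio(self) -> float:
        """Asymptotic daughter/parent activity ratio lam_b/(lam_b - lam_a).

        For 225Ac/213Bi this is ~1.003; some analyses round it to 1.
        """
        la, lb = self.lam_parent, self.lam_daughter
        _require_faster_daughter(la, lb)
        return lb / (lb - la)

    @property
    def total_alpha_energy(self) -> float:
        """Branching-weighted alpha energy per chain decay, MeV."""
        return sum(n.alpha_yield * n.alpha_energy for n in self.nuclides)


# Alpha energies are standard nuclear-data values (intensity-weighted
# means); the yields per chain decay follow from the 2.1% alpha branch of
# 213Bi.  All values are overridable via configuration.
AC225_CHAIN = DecayChain(
    (
        Nuclide("Ac-225", 9.9 * SECONDS_PER_DAY, alpha_energy=5.79, alpha_yield=1.0),
        Nuclide("Fr-221", 4.8 * 60.0, alpha_energy=6.30, alpha_yield=1.0),
        Nuclide("At-217", 32e-3, alpha_energy=7.07, alpha_yield=1.0),
        Nuclide("Bi-213", 45.6 * 60.0, alpha_energy=5.87, alpha_yield=0.021),
        Nuclide("Po-213", 3.72e-6, alpha_energy=8.38, alpha_yield=0.979),
    )
)


@dataclass
class RatioSeries:
    """Daughter/parent activity ratios measured at times post-sacrifice."""

    times: np.ndarray
    ratios: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.ratios.shape:
            raise ValueError("times and ratios must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be positive")


def _require_faster_daughter(lam_a: float, lam_b: float) -> None:
    if lam_b <= lam_a:
        raise ValueError(
            "daughter decay constant must exceed the parent's "
            f"(lam_b={lam_b:.3e} <= lam_a={lam_a:.3e})"
        )


def ratio_at_time(r0: float, t: float | np.ndarray, chain: DecayChain) -> float | np.ndarray:
    """Daughter/parent activity ratio at time ``t`` after sacrifice.

    With r(t) = A_b(t)/A_a(t) and k = lam_b/(lam_b - lam_a),

        r(t) = (r0 - k) e^{-(lam_b - lam_a) t} + k

    so any initial excess or deficit of the daughter relaxes toward the
    transient-equilibrium ratio k with rate lam_b - lam_a.
    """
    la, lb = chain.lam_parent, chain.lam_daughter
    _require_faster_daughter(la, lb)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    k = lb / (lb - la)
    out = (r0 - k) * np.exp(-(lb - la) * t) + k
    return float(out) if out.ndim == 0 else out


def initial_daughter_activity(
    Ab_t: float, Aa_t: float, t: float, chain: DecayChain
) -> float:
    """Daughter activity at sacrifice from activities measured at time ``t``.

    Inverts :func:`ratio_at_time`:

        A_b(0) = A_b(t) e^{lam_b t} - k A_a(t) (e^{lam_b t} - e^{lam_a t})

    with k = lam_b/(lam_b - lam_a).
    """
    la, lb = chain.lam_parent, chain.lam_daughter
    _require_faster_daughter(la, lb)
    if t < 0:
        raise ValueError("t must be >= 0")
    if Ab_t < 0 or Aa_t < 0:
        raise ValueError("activities must be >= 0")
    k = lb / (lb - la)
    return Ab_t * math.exp(lb * t) - k * Aa_t * (math.exp(lb * t) - math.exp(la * t))


def fit_initial_ratio(series: RatioSeries, chain: DecayChain) -> tuple[float, float]:
    """Least-squares estimate of the sacrifice-time ratio r0 = A_b(0)/A_a(0).

    The model r(t) = k + (r0 - k) g(t) with g(t) = e^{-(lam_b - lam_a) t}
    is linear in r0, so the weighted least-squares solution is closed
    form.  Returns ``(r0, r_squared)`` where r_squared is the ordinary
    coefficient of determination of the fit (1 for a noiseless series).
    """
    la, lb = chain.lam_parent, chain.lam_daughter
    _require_faster_daughter(la, lb)
    t = series.times
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    k = lb / (lb - la)
    g = np.exp(-(lb - la) * t)
    w = (
        1.0 / series.uncertainties**2
        if series.uncertainties is not None
        else np.ones_like(t)
    )
    denom = np.sum(w * g * g)
    if denom <= 0:
        raise ValueError("degenerate design: no usable time points")
    r0 = k + float(np.sum(w * g * (series.ratios - k)) / denom)
    pred = k + (r0 - k) * g
    ss_res = float(np.sum((series.ratios - pred) ** 2))
    ss_tot = float(np.sum((series.ratios - series.ratios.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return r0, r2


def free_daughter_excess(
    Ab0: float, Aa0: float, equilibrium_tol: float = 0.05
) -> tuple[float, str]:
    """Free (redistributed) daughter activity at sacrifice.

    Returns ``(excess, status)`` where excess = max(A_b(0) - A_a(0), 0)
    and status is ``"equilibrium"`` when the ratio is within
    ``equilibrium_tol`` of 1 (ratios like 0.97 +/- 0.04 are treated as
    secular equilibrium), ``"excess"`` for a true surplus, and
    ``"deficit"`` when the daughter is depleted (e.g. blood, from which
    free 213Bi is cleared).
    """
    if Ab0 < 0 or Aa0 < 0:
        raise ValueError("activities must be >= 0")
    excess = Ab0 - Aa0
    if Aa0 > 0 and abs(Ab0 / Aa0 - 1.0) <= equilibrium_tol:
        return 0.0, "equilibrium"
    if excess < 0:
        return 0.0, "deficit"
    return excess, "excess"


def frame_coincidence_factor(
    frame_period: float, daughter_half_life: float, alphas_per_chain: float
) -> float:
    """Count-loss correction for parent/daughter alphas sharing a camera frame.

    When a progeny half-life (217At, 32 ms) is on the order of the frame
    period (40 ms at 25 FPS), the parent and daughter alphas can land in
    the same frame at nearly the same position and be counted as one
    event.  Modelling the parent decay time as uniform within the frame
    and the daughter delay as exponential, the same-frame probability is

        P = 1 - (1 - e^{-lam T}) / (lam T)

    and the multiplicative correction to the total count rate is
    ``1 / (1 - P / m)`` with m alphas per chain.  At T = 40 ms,
    t1/2 = 32 ms and m = 4 this evaluates to 1.09.
    """
    if frame_period <= 0 or daughter_half_life <= 0:
        raise ValueError("frame_period and daughter_half_life must be > 0")
    if alphas_per_chain < 1:
        raise ValueError("alphas_per_chain must be >= 1")
    lam = math.log(2.0) / daughter_half_life
    x = lam * frame_period
    p_same = 1.0 - (-math.expm1(-x)) / x
    return 1.0 / (1.0 - p_same / alphas_per_chain)


def simulate_frame_coincidence(
    frame_period: float,
    daughter_half_life: float,
    n_pairs: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Monte Carlo estimate of the same-frame coincidence probability.

    Draws ``n_pairs`` parent decays uniform within a frame and daughter
    delays exponential with the daughter's decay constant; a pair
    coincides when the daughter decay falls in the same frame.  Returns
    ``(p_hat, sigma)`` with the binomial standard error.
    """
    rng = np.random.default_rng(rng)
    lam = math.log(2.0) / daughter_half_life
    t_parent = rng.uniform(0.0, frame_period, size=n_pairs)
    delay = rng.exponential(1.0 / lam, size=n_pairs)
    same = t_parent + delay < frame_period
    p_hat = float(np.mean(same))
    sigma = math.sqrt(max(p_hat * (1.0 - p_hat), 1e-300) / n_pairs)
    return p_hat, sigma


def decay_correct(
    value: float | np.ndarray, elapsed: float, half_life: float
) -> float | np.ndarray:
    """Correct a count or activity back over ``elapsed`` seconds of decay.

    Multiplies by 2^{elapsed/half_life}; a negative ``elapsed`` corrects
    forward in time.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    return value * 2.0 ** (elapsed / half_life)
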