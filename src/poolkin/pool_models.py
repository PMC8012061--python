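"""Reversible two-pool priming models and recovery-curve analysis.

A large upstream depot pool (DP) fills a primed pool (PP) through a
reversible priming step (forward rate constant k1, reverse "depriming"
rate constant k_-1); fusion removes primed vesicles with rate constant k_f.
DP is assumed constant, so the forward flux is the lumped rate k1*DP.

Model I (no release sites; the chromaffin-cell case):

    dPP/dt = k1*DP - (k_-1 + k_f) * PP,      k1*DP in fF/s

with recovery time constant 1/(k_-1 + k_f) and steady state
k1*DP / (k_-1 + k_f).

Model II (release-site-limited; the "neuronal" case) caps the primed pool
at PP_max, with k1*DP now per release site (s^-1):

    dPP/dt = k1*DP * (PP_max - PP) - (k_-1 + k_f) * PP

whose recovery time constant 1/(k_-1 + k_f + k1*DP) is sped up by the
forward rate, and steady state is k1*DP * PP_max / (k_-1 + k_f + k1*DP).

Paired-flash recovery experiments (two uncaging stimuli separated by a
varying interval, k_f = 0 between stimuli) measure the ratio Stim2/Stim1 of
pool estimates; a mono-exponential fit plateau*(1 - exp(-rate*dt)) yields
the depriming rate directly under Model I, and together with the
steady-state pool size the forward priming rate before (k_-1 * pool) and
after stimulation (scaled by the fitted plateau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "Model1Params",
    "Model2Params",
    "RecoveryCurve",
    "RecoveryFit",
    "DerivedRates",
    "model1_pool",
    "model2_pool",
    "steady_state",
    "fit_recovery",
    "derive_rates",
    "translate_to_release_site",
    "simulate_recovery",
    "ode_oracle",
]


@dataclass(frozen=True)
class Model1Params:
    """Free-pool (Model I) rate constants; k1dp is the lumped k1*DP in fF/s."""

    k1dp: float  # fF/s
    k_minus1: float  # s^-1
    k_f: float = 0.0  # s^-1; 0 between stimuli

    def __post_init__(self) -> None:
        if self.k1dp < 0 or self.k_minus1 < 0 or self.k_f < 0:
            raise ValueError("rate constants must be non-negative")
        if self.k_minus1 + self.k_f <= 0:
            raise ValueError("k_minus1 + k_f must be positive for a steady state")


@dataclass(frozen=True)
class Model2Params:
    """Release-site (Model II) parameters; k1dp is per release site, s^-1."""

    k1dp: float  # s^-1
    pp_max: float  # fF, release-site capacity
    k_minus1: float  # s^-1
    k_f: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if self.k1dp < 0 or self.k_minus1 < 0 or self.k_f < 0:
            raise ValueError("rate constants must be non-negative")
        if self.pp_max <= 0:
            raise ValueError("pp_max must be positive")


@dataclass
class RecoveryCurve:
    """Per-cell paired-flash recovery ratios vs inter-stimulus interval.

    ``intervals`` and ``ratios`` are parallel flat arrays, one entry per
    simulated or recorded cell; ``readout`` records which post-flash time
    (0.06 or 0.6 s) the pool estimate came from.
    """

    intervals: np.ndarray  # s, one per cell
    ratios: np.ndarray  # Stim2/Stim1, dimensionless
    readout: float = 0.06

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.intervals.shape != self.ratios.shape:
            raise ValueError("intervals and ratios must be parallel arrays")
        if np.any(self.intervals <= 0):
            raise ValueError("inter-stimulus intervals must be positive")

    def interval_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique intervals and the mean ratio at each."""
        uniq = np.unique(self.intervals)
        means = np.array([self.ratios[self.intervals == u].mean() for u in uniq])
        return uniq, means


@dataclass(frozen=True)
class RecoveryFit:
    """Mono-exponential recovery fit: ratio(dt) = plateau*(1 - exp(-rate*dt))."""

    plateau: float
    rate: float  # s^-1; k_-1 + k_f (+ k1dp under Model II)
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.plateau < 0:
            raise ValueError("plateau must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class DerivedRates:
    """Priming/depriming rates derived from a recovery fit and a pool size."""

    k_minus1: float  # s^-1
    k1dp_before: float  # fF/s
    k1dp_after: float  # fF/s
    pool_size: float  # fF

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# closed-form pools
# ---------------------------------------------------------------------------


def model1_pool(t, p: Model1Params, pp0: float = 0.0):
    """Primed pool under Model I at time(s) ``t`` (s), starting from pp0.

    PP(t) = ss + (pp0 - ss) * exp(-(k_-1 + k_f) * t), ss = k1dp/(k_-1 + k_f).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam = p.k_minus1 + p.k_f
    ss = p.k1dp / lam
    out = ss + (pp0 - ss) * np.exp(-lam * t)
    return float(out) if out.ndim == 0 else out


def model2_pool(t, p: Model2Params, pp0: float = 0.0):
    """Primed pool under Model II; recovery is sped up by the forward rate."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam = p.k_minus1 + p.k_f + p.k1dp
    if lam <= 0:
        out = np.full_like(t, float(pp0))
        return float(out) if out.ndim == 0 else out
    ss = p.k1dp * p.pp_max / lam
    out = ss + (pp0 - ss) * np.exp(-lam * t)
    return float(out) if out.ndim == 0 else out


def steady_state(p: Model1Params | Model2Params) -> float:
    """Equilibrium primed-pool size (fF)."""
    if isinstance(p, Model1Params):
        return p.k1dp / (p.k_minus1 + p.k_f)
    lam = p.k_minus1 + p.k_f + p.k1dp
    return p.k1dp * p.pp_max / lam if lam > 0 else 0.0


def _pool(t, p, pp0=0.0):
    return model1_pool(t, p, pp0) if isinstance(p, Model1Params) else model2_pool(t, p, pp0)


# ---------------------------------------------------------------------------
# recovery analysis
# ---------------------------------------------------------------------------


def fit_recovery(
    curve: RecoveryCurve,
    mode: Literal["points", "means"] = "points",
) -> RecoveryFit:
    """Least-squares mono-exponential fit of a recovery curve.

    By default every per-cell (interval, ratio) point enters the fit;
    ``mode="means"`` fits the per-interval means instead.  Under Model I
    with k_f = 0 the fitted rate estimates the depriming rate k_-1.
    Raises on degenerate input (fewer than 3 distinct intervals, or all
    ratios identical so the rate is unidentifiable).
    """
    if np.unique(curve.intervals).size < 3:
        raise ValueError("need at least 3 distinct inter-stimulus intervals")
    if mode == "means":
        x, y = curve.interval_means()
    else:
        x, y = curve.intervals, curve.ratios
    if np.allclose(y, y[0]):
        raise ValueError("degenerate recovery curve: all ratios equal")

    def residual(q):
        plateau, rate = q
        return plateau * -np.expm1(-rate * x) - y

    plateau0 = max(float(np.max(y)), 0.1)
    best = None
    for rate0 in np.geomspace(1e-3, 2.0, 8):
        sol = least_squares(
            residual, np.array([plateau0, rate0]),
            bounds=(np.array([0.0, 1e-8]), np.array([np.inf, np.inf])),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    plateau, rate = best.x
    return RecoveryFit(plateau=float(plateau), rate=float(rate),
                       rss=float(2 * best.cost))


def derive_rates(pool_size: float, fit: RecoveryFit) -> DerivedRates:
    """Translate a recovery fit and steady-state pool size into rates.

    With k_f = 0 between stimuli the fitted rate is k_-1; the steady state
    gives the pre-stimulation forward rate k1*DP = k_-1 * pool; the fitted
    plateau (Stim2/Stim1 at infinite interval) rescales it to the
    post-stimulation forward rate.
    """
    if pool_size < 0:
        raise ValueError("pool_size must be non-negative")
    k_minus1 = fit.rate
    before = k_minus1 * pool_size
    return DerivedRates(
        k_minus1=k_minus1,
        k1dp_before=before,
        k1dp_after=before * fit.plateau,
        pool_size=pool_size,
    )


def translate_to_release_site(
    pool_size: float,
    recovery_rate: float,
    occupancy: float = 0.9,
) -> Model2Params:
    """Model I estimates -> Model II parameters with identical recovery.

    Assuming the primed pool sits at ``occupancy`` of capacity at rest
    (k_f = 0), the capacity is pool/occupancy and the pair (k1dp, k_-1)
    solves  k_-1 + k1dp = recovery_rate  and
    k1dp*pp_max/(k_-1 + k1dp) = pool_size, giving in closed form

        k1dp = recovery_rate * occupancy,
        k_-1 = recovery_rate * (1 - occupancy).

    Model II recovery with these parameters has the same time constant and
    steady state as the Model I input.
    """
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if recovery_rate <= 0:
        raise ValueError("recovery_rate must be positive")
    if pool_size <= 0:
        raise ValueError("pool_size must be positive")
    return Model2Params(
        k1dp=recovery_rate * occupancy,
        pp_max=pool_size / occupancy,
        k_minus1=recovery_rate * (1 - occupancy),
        k_f=0.0,
    )


def simulate_recovery(
    p: Model1Params | Model2Params,
    k1dp_after: float,
    intervals: Iterable[float],
) -> RecoveryCurve:
    """Noiseless paired-flash recovery ratios under either model.

    The first stimulus empties a pool at its pre-stimulation steady state;
    recovery then proceeds from zero with the forward rate switched to
    ``k1dp_after`` (same unit as ``p.k1dp``).  Ratios are Stim2/Stim1.
    """
    intervals = np.asarray(list(intervals), dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    stim1 = steady_state(p)
    if stim1 <= 0:
        raise ValueError("pre-stimulation steady state must be positive")
    p_after = replace(p, k1dp=k1dp_after)
    stim2 = _pool(intervals, p_after, 0.0)
    return RecoveryCurve(intervals=intervals, ratios=stim2 / stim1)


def ode_oracle(
    p: Model1Params | Model2Params,
    t_end: float,
    pp0: float = 0.0,
    n_points: int = 201,
) -> tuple[np.ndarray, np.ndarray]:
    """Numerical integration of the pool ODE; independent check of the
    closed forms (test use only)."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    if isinstance(p, Model1Params):
        def rhs(_t, y):
            return [p.k1dp - (p.k_minus1 + p.k_f) * y[0]]
    else:
        def rhs(_t, y):
            return [p.k1dp * (p.pp_max - y[0]) - (p.k_minus1 + p.k_f) * y[0]]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), [float(pp0)], t_eval=t_eval,
                    method="LSODA", rtol=1e-11, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y[0]
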