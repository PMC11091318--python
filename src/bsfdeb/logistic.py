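"""Kinetic growth model: Verhulst logistic growth with a growth-plus-
maintenance CO2 partition.

Larval mass follows the logistic curve
``X(t) = Xmax / (1 + ((Xmax - X0)/X0) exp(-mu t))`` and respiration is
split Pirt-style into a growth-associated and a maintenance term,
``r_CO2 = Y r_X + m X`` — the same structure as the classical model for
growth-associated product formation in microbial cultures.  Growth and CO2
production together give the feed assimilation rate, which cannot be
measured directly by mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "PirtParams",
    "VerhulstFit",
    "verhulst_weight",
    "kinetic_growth_rate",
    "kinetic_respiration_rate",
    "kinetic_assimilation_rate",
    "fit_verhulst",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a series has too few points to constrain the model."""


@dataclass(frozen=True)
class LogisticParams:
    """mu: maximal specific growth rate (1/day); X0, Xmax: initial and
    asymptotic larval mass (mg C)."""

    mu: float
    X0: float
    Xmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError("mu must be positive and finite")
        if not 0 < self.X0 < self.Xmax:
            raise ValueError("require 0 < X0 < Xmax")


@dataclass(frozen=True)
class PirtParams:
    """Y: cost of growth (mg C respired per mg C incorporated);
    m: maintenance coefficient (1/day)."""

    Y: float = 0.44
    m: float = 0.08

    def __post_init__(self) -> None:
        if self.Y < 0 or self.m < 0:
            raise ValueError("Y and m must be >= 0")


def verhulst_weight(t, p: LogisticParams):
    """Closed-form logistic weight X(t) in mg C; t in days, t >= 0."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("t must be finite and >= 0")
    out = p.Xmax / (1.0 + (p.Xmax - p.X0) / p.X0 * np.exp(-p.mu * t))
    return float(out) if out.ndim == 0 else out


def kinetic_growth_rate(X, p: LogisticParams):
    """Logistic growth rate r_X = mu X (1 - X/Xmax), mg C/day."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X > p.Xmax):
        raise ValueError("X must lie in [0, Xmax]")
    out = p.mu * X * (1.0 - X / p.Xmax)
    return float(out) if out.ndim == 0 else out


def kinetic_respiration_rate(r_X, X, q: PirtParams):
    """Total respiration r_CO2 = Y r_X + m X (mg C/day): growth-associated
    plus maintenance CO2."""
    r_X = np.asarray(r_X, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(r_X < 0) or np.any(X < 0):
        raise ValueError("r_X and X must be >= 0")
    out = q.Y * r_X + q.m * X
    return float(out) if out.ndim == 0 else out


def kinetic_assimilation_rate(r_X, r_CO2):
    """Feed assimilation rate r_A = r_X + r_CO2 (mg C/day)."""
    r_X = np.asarray(r_X, dtype=float)
    r_CO2 = np.asarray(r_CO2, dtype=float)
    if np.any(r_X < 0) or np.any(r_CO2 < 0):
        raise ValueError("rates must be >= 0")
    out = r_X + r_CO2
    return float(out) if out.ndim == 0 else out


@dataclass
class VerhulstFit:
    params: LogisticParams | None
    rss: float
    converged: bool
    message: str
    n_starts: int

    @property
    def degenerate(self) -> bool:
        return not self.converged or self.params is None


def fit_verhulst(t, X, *, n_starts: int = 8, seed: int = 0) -> VerhulstFit:
    """Multi-start bounded least squares fit of the logistic curve.

    Bounds: mu in (0, 3], Xmax in (max(X), 10 max(X)], X0 in (0, max(X)).
    A series with no growth signal (e.g. constant weights) is reported as
    degenerate rather than returning a spurious estimate.
    """
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    if len(np.unique(t)) < 4:
        raise InsufficientDataError("need >= 4 distinct time points")
    if np.any(X <= 0):
        raise ValueError("weights must be positive")
    xmax_obs = float(np.max(X))

    # flat series carry no curvature to fit
    if np.ptp(X) < 1e-12 * xmax_obs:
        return VerhulstFit(params=None, rss=float("nan"), converged=False,
                           message="no growth signal (constant series)",
                           n_starts=0)

    lo = np.array([1e-6, 1e-9 * xmax_obs, xmax_obs * (1 + 1e-9)])
    hi = np.array([3.0, xmax_obs, 10.0 * xmax_obs])

    def resid(theta):
        mu, x0, xmax = theta
        pred = xmax / (1.0 + (xmax - x0) / x0 * np.exp(-mu * (t - t[0])))
        return pred - X

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        if i == 0:
            theta0 = np.array([0.5, max(X[np.argmin(t)], lo[1]),
                               1.05 * xmax_obs])
        else:
            u = rng.uniform(size=3)
            theta0 = lo + u * (hi - lo)
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(resid, theta0, bounds=(lo, hi),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return VerhulstFit(params=None, rss=float("nan"), converged=False,
                           message="optimizer failed to converge",
                           n_starts=n_starts)
    mu, x0, xmax = best.x
    try:
        params = LogisticParams(mu=mu, X0=x0, Xmax=xmax)
    except ValueError as exc:
        return VerhulstFit(params=None, rss=2 * best.cost, converged=False,
                           message=f"degenerate estimate: {exc}",
                           n_starts=n_starts)
    return VerhulstFit(params=params, rss=2 * best.cost, converged=True,
                       message=best.message, n_starts=n_starts)
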