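"""Equilibria, reproduction numbers and outbreak thresholds.

The degree-structured system admits a disease-free equilibrium
``(bN/d, 0, 0)`` in every degree class, and an endemic equilibrium exactly
when the self-consistency equation for the infected-edge fraction Theta has
a root in (0, 1]. Writing

    F(Theta) = Theta - (1/<k>) sum_k  b N beta (1-delta) k^2 p(k) Theta
               / ( [d + beta k (1-delta) Theta] [gamma (1+lam) + d] )

one has F(0) = 0, F(1) > 0 and F convex, so a nontrivial root exists iff
F'(0) < 0, which is equivalent to R0 > 1 with

    R0 = b N beta (1-delta) / (d^2 + gamma d (1+lam)) * C,

where the connectivity factor C is <k^2>/<k> on heterogeneous networks and
<k> on homogeneous ones. The outbreak threshold beta_c is the infection
rate at which R0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import bisect

from .core import (
    DegreeDistribution,
    EpidemicParams,
    EquilibriumPoint,
    ParameterError,
)

__all__ = [
    "OutbreakSummary",
    "disease_free_equilibrium",
    "auxiliary_F",
    "solve_endemic_theta",
    "endemic_equilibrium",
    "basic_reproduction_number",
    "outbreak_threshold",
    "outbreak_summary",
    "sensitivity_grid",
]

NetworkClass = Literal["homogeneous", "heterogeneous"]

#: |R0 - 1| below this is reported as the critical regime.
CRITICAL_BAND = 1e-9


@dataclass(frozen=True)
class OutbreakSummary:
    """R0, threshold and regime for one parameter set on one network class."""

    R0: float
    beta_c: float
    endemic_theta: Optional[float]
    regime: Literal["subcritical", "critical", "supercritical"]


def _require_positive_death(params: EpidemicParams) -> None:
    if params.d <= 0:
        raise ParameterError("d must be > 0 for equilibrium/threshold analysis")


def disease_free_equilibrium(
    params: EpidemicParams, dist: Optional[DegreeDistribution] = None
) -> EquilibriumPoint:
    """The always-present disease-free point ``(bN/d, 0, 0)`` per class."""
    _require_positive_death(params)
    m = 1 if dist is None else dist.degrees.size
    s_star = params.b * params.N / params.d
    zeros = np.zeros(m)
    return EquilibriumPoint(
        kind="disease_free", Sk=np.full(m, s_star), Ik=zeros, Rk=zeros.copy(), theta=0.0
    )


def auxiliary_F(theta: float, params: EpidemicParams, dist: DegreeDistribution) -> float:
    """The self-consistency residual F(Theta); roots in (0, 1] are endemic."""
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta must lie in [0, 1], got {theta}")
    _require_positive_death(params)
    k = dist.degrees.astype(np.float64)
    num = params.b * params.N * params.beta_eff * k**2 * dist.probs * theta
    den = (params.d + params.beta_eff * k * theta) * (params.gamma_eff + params.d)
    return float(theta - np.sum(num / den) / dist.mean_degree)


def solve_endemic_theta(
    params: EpidemicParams, dist: DegreeDistribution
) -> Optional[float]:
    """Nontrivial root of F in (0, 1], or None when the system is subcritical.

    The root exists iff F'(0) < 0 (equivalently R0 > 1); convexity of F
    makes it unique, so bracketed bisection is exact enough. The bracket is
    [eps, 1] when F(1) > 0 — guaranteed whenever bN < gamma (1+lam) + d, so
    per-class densities stay below one — and is otherwise widened to the a
    priori bound Theta* <= bN / (gamma (1+lam) + d) that follows from the
    endemic I_k expression (the stationary population bN/d may exceed one,
    and Theta scales with it).
    """
    _require_positive_death(params)
    # F'(0) = 1 - R0 with the heterogeneous connectivity factor.
    r0 = basic_reproduction_number(params, dist, "heterogeneous")
    if r0 <= 1.0:
        return None

    def residual(theta: float) -> float:
        k = dist.degrees.astype(np.float64)
        num = params.b * params.N * params.beta_eff * k**2 * dist.probs * theta
        den = (params.d + params.beta_eff * k * theta) * (params.gamma_eff + params.d)
        return float(theta - np.sum(num / den) / dist.mean_degree)

    lo, hi = 1e-12, 1.0
    if residual(lo) >= 0:  # root indistinguishable from zero at this scale
        return None
    if residual(hi) <= 0:
        hi = params.b * params.N / (params.gamma_eff + params.d) * (1.0 + 1e-9)
    root = bisect(residual, lo, hi, xtol=1e-15, maxiter=200)
    return float(root)


def endemic_equilibrium(
    params: EpidemicParams, dist: DegreeDistribution
) -> Optional[EquilibriumPoint]:
    """Endemic equilibrium from the fixed-point Theta*, or None below threshold.

    S_k* = bN / (d + beta k (1-delta) Theta*),
    I_k* = bN beta k Theta* (1-delta) / ([d + beta k Theta* (1-delta)] [gamma(1+lam) + d]),
    R_k* = gamma (1+lam) I_k* / d.
    """
    theta = solve_endemic_theta(params, dist)
    if theta is None:
        return None
    k = dist.degrees.astype(np.float64)
    denom = params.d + params.beta_eff * k * theta
    Sk = params.b * params.N / denom
    Ik = params.b * params.N * params.beta_eff * k * theta / (
        denom * (params.gamma_eff + params.d)
    )
    Rk = params.gamma_eff * Ik / params.d
    return EquilibriumPoint(kind="endemic", Sk=Sk, Ik=Ik, Rk=Rk, theta=theta)


def _connectivity_factor(dist: DegreeDistribution, network_class: NetworkClass) -> float:
    if network_class == "heterogeneous":
        return dist.connectivity_ratio
    if network_class == "homogeneous":
        return dist.mean_degree
    raise ParameterError(f"unknown network_class {network_class!r}")


def basic_reproduction_number(
    params: EpidemicParams,
    dist: DegreeDistribution,
    network_class: NetworkClass = "heterogeneous",
) -> float:
    """R0 = bN beta (1-delta) C / (d^2 + gamma d (1+lam)).

    C is the connectivity factor: ``<k^2>/<k>`` (heterogeneous) or ``<k>``
    (homogeneous). Diverges as d -> 0, hence d > 0 is required.
    """
    _require_positive_death(params)
    c = _connectivity_factor(dist, network_class)
    denom = params.d**2 + params.gamma * params.d * (1.0 + params.lam)
    return params.b * params.N * params.beta_eff * c / denom


def outbreak_threshold(
    params: EpidemicParams,
    dist: DegreeDistribution,
    network_class: NetworkClass = "heterogeneous",
) -> float:
    """Critical infection rate beta_c at which R0 crosses 1.

    beta_c = (d^2 + gamma d (1+lam)) / (bN (1-delta) C). Infinite (and
    rejected) when delta = 1 or b = 0: no transmission or no susceptible
    inflow means no threshold exists.
    """
    _require_positive_death(params)
    if params.delta >= 1.0:
        raise ParameterError("delta = 1 shuts off transmission; threshold is infinite")
    if params.b <= 0:
        raise ParameterError("b = 0 gives no susceptible inflow; threshold is infinite")
    c = _connectivity_factor(dist, network_class)
    denom = params.d**2 + params.gamma * params.d * (1.0 + params.lam)
    return denom / (params.b * params.N * (1.0 - params.delta) * c)


def outbreak_summary(
    params: EpidemicParams,
    dist: DegreeDistribution,
    network_class: NetworkClass = "heterogeneous",
) -> OutbreakSummary:
    """R0, beta_c, endemic Theta* (if any) and the resulting regime."""
    r0 = basic_reproduction_number(params, dist, network_class)
    try:
        beta_c = outbreak_threshold(params, dist, network_class)
    except ParameterError:
        beta_c = float("inf")
    if network_class == "heterogeneous":
        theta = solve_endemic_theta(params, dist)
    else:
        theta = _homogeneous_theta(params, dist.mean_degree)
    if abs(r0 - 1.0) <= CRITICAL_BAND:
        regime = "critical"
    elif r0 > 1.0:
        regime = "supercritical"
    else:
        regime = "subcritical"
    return OutbreakSummary(R0=r0, beta_c=beta_c, endemic_theta=theta, regime=regime)


def _homogeneous_theta(params: EpidemicParams, k_mean: float) -> Optional[float]:
    """Closed-form root of the scalar (single-class) self-consistency equation.

    With x = beta (1-delta) <k> and y = gamma (1+lam) + d the equation
    Theta = bN x Theta / ((d + x Theta) y) has the nontrivial root
    Theta* = (bN x / y - d) / x, positive exactly when R0 > 1.
    """
    x = params.beta_eff * k_mean
    if x <= 0:
        return None
    theta = (params.b * params.N * x / (params.gamma_eff + params.d) - params.d) / x
    return theta if theta > 0 else None


def sensitivity_grid(
    params: EpidemicParams,
    pair: Tuple[str, str],
    ranges: Tuple[Sequence[float], Sequence[float]],
    dist: DegreeDistribution,
    network_class: NetworkClass = "heterogeneous",
) -> np.ndarray:
    """R0 over a 2-D grid of one parameter pair, all others held fixed.

    ``pair`` is one of ("beta", "gamma"), ("delta", "lam"), ("b", "d");
    ``ranges`` are the two grid axes. Returns a matrix with the first
    parameter varying along rows and the second along columns.
    """
    allowed = {("beta", "gamma"), ("delta", "lam"), ("b", "d")}
    if tuple(pair) not in allowed:
        raise ParameterError(f"pair must be one of {sorted(allowed)}, got {pair}")
    ax0 = np.asarray(ranges[0], dtype=np.float64)
    ax1 = np.asarray(ranges[1], dtype=np.float64)
    grid = np.empty((ax0.size, ax1.size))
    for i, v0 in enumerate(ax0):
        for j, v1 in enumerate(ax1):
            p = params.replace(**{pair[0]: float(v0), pair[1]: float(v1)})
            grid[i, j] = basic_reproduction_number(p, dist, network_class)
    return grid
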