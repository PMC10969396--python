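"""Mean-field ODE layer: homogeneous and degree-structured systems.

Homogeneous system (densities, connectivity through the mean degree <k>):

    dS/dt = b N - d S - beta (1 - delta) <k> S I
    dI/dt = beta (1 - delta) <k> S I - gamma (1 + lam) I - d I
    dR/dt = gamma (1 + lam) I - d R

The heterogeneous (degree-based) system tracks one (S_k, I_k, R_k) triple
per degree class and couples classes only through the infected-edge fraction

    Theta = (1 / <k>) * sum_k k p(k) I_k .

Newborn handling: in SPES mode the inflow ``b N`` feeds the transmitting
susceptible class directly; in SNES mode it feeds a passive pool P with
dP/dt = b N - d P that is *reported* as part of S(t) but never appears in
the infection term, so the disease always dies out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    DegreeDistribution,
    EpidemicParams,
    ParameterError,
    SimulationConfig,
    Trajectory,
)

__all__ = [
    "HeterogeneousState",
    "HeterogeneousDerivatives",
    "infected_edge_fraction",
    "homogeneous_rhs",
    "heterogeneous_rhs",
    "integrate_meanfield",
    "total_population_closed_form",
]


@dataclass
class HeterogeneousState:
    """Per-degree-class densities aligned with a DegreeDistribution support."""

    Sk: np.ndarray
    Ik: np.ndarray
    Rk: np.ndarray

    def __post_init__(self) -> None:
        self.Sk = np.asarray(self.Sk, dtype=np.float64)
        self.Ik = np.asarray(self.Ik, dtype=np.float64)
        self.Rk = np.asarray(self.Rk, dtype=np.float64)
        if not (self.Sk.shape == self.Ik.shape == self.Rk.shape):
            raise ParameterError("Sk, Ik, Rk must have identical shapes")
        if np.any(self.Sk < 0) or np.any(self.Ik < 0) or np.any(self.Rk < 0):
            raise ParameterError("state densities must be non-negative")


@dataclass
class HeterogeneousDerivatives:
    """Per-degree-class time derivatives (sign-unconstrained)."""

    Sk: np.ndarray
    Ik: np.ndarray
    Rk: np.ndarray


def infected_edge_fraction(Ik: Sequence[float], dist: DegreeDistribution) -> float:
    """Infected-edge fraction Theta = (1/<k>) sum_k k p(k) I_k.

    The probability that an edge of a susceptible node points at an infected
    node, under the uncorrelated-network (annealed) approximation.
    """
    Ik = np.asarray(Ik, dtype=np.float64)
    if Ik.shape != dist.degrees.shape:
        raise ParameterError(
            f"Ik length {Ik.size} does not match degree support {dist.degrees.size}"
        )
    if np.any(Ik < 0):
        raise ParameterError("Ik entries must be non-negative")
    km = dist.mean_degree
    if km == 0:
        raise ParameterError("mean degree is zero; Theta undefined")
    return float(np.dot(dist.degrees * dist.probs, Ik) / km)


def homogeneous_rhs(
    state: Sequence[float],
    params: EpidemicParams,
    k_mean: float,
    newborn_mode: str = "SPES",
):
    """Time derivatives of the homogeneous system.

    ``state`` is (S, I, R) in SPES mode and (S, I, R, P) in SNES mode, where
    P is the passive newborn pool. Returns the derivative tuple of the same
    length.
    """
    if k_mean <= 0:
        raise ParameterError(f"k_mean must be > 0, got {k_mean}")
    state = np.asarray(state, dtype=np.float64)
    if np.any(state < 0):
        raise ParameterError("state entries must be non-negative")
    infect = params.beta_eff * k_mean * state[0] * state[1]
    recover = params.gamma_eff * state[1]
    inflow = params.b * params.N
    dS = -params.d * state[0] - infect
    dI = infect - recover - params.d * state[1]
    dR = recover - params.d * state[2]
    if newborn_mode == "SPES":
        return (dS + inflow, dI, dR)
    if newborn_mode == "SNES":
        if state.size != 4:
            raise ParameterError("SNES state must include the passive pool (S, I, R, P)")
        dP = inflow - params.d * state[3]
        return (dS, dI, dR, dP)
    raise ParameterError(f"unknown newborn_mode {newborn_mode!r}")


def heterogeneous_rhs(
    state: HeterogeneousState,
    params: EpidemicParams,
    dist: DegreeDistribution,
    newborn_mode: str = "SPES",
    passive: float = 0.0,
):
    """Per-degree-class derivatives of the degree-structured system.

    Returns a :class:`HeterogeneousDerivatives` (plus the passive pool
    derivative as a second return value in SNES mode).
    """
    if state.Sk.shape != dist.degrees.shape:
        raise ParameterError("state not aligned with the degree support")
    theta = infected_edge_fraction(state.Ik, dist)
    k = dist.degrees.astype(np.float64)
    infect = params.beta_eff * k * state.Sk * theta
    recover = params.gamma_eff * state.Ik
    inflow = params.b * params.N
    dSk = -params.d * state.Sk - infect
    dIk = infect - recover - params.d * state.Ik
    dRk = recover - params.d * state.Rk
    if newborn_mode == "SPES":
        return HeterogeneousDerivatives(Sk=dSk + inflow, Ik=dIk, Rk=dRk)
    if newborn_mode == "SNES":
        dP = inflow - params.d * passive
        return HeterogeneousDerivatives(Sk=dSk, Ik=dIk, Rk=dRk), dP
    raise ParameterError(f"unknown newborn_mode {newborn_mode!r}")


def integrate_meanfield(
    params: EpidemicParams,
    connectivity: Union[DegreeDistribution, float],
    init,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the mean-field system on the uniform reporting grid.

    Parameters
    ----------
    connectivity
        A :class:`DegreeDistribution` selects the heterogeneous system; a
        plain float is the mean degree of the homogeneous system.
    init
        Homogeneous: an (S0, I0, R0) triple. Heterogeneous: an
        :class:`HeterogeneousState` aligned with the distribution support.
    config
        Supplies the grid and the newborn mode. In SNES mode the reported
        S(t) includes the passive pool, so the plotted proportion matches
        the SPES total-population law.

    Uses LSODA (adaptive, stiff-capable) with rtol 1e-10.
    """
    heterogeneous = isinstance(connectivity, DegreeDistribution)
    snes = config.newborn_mode == "SNES"

    if heterogeneous:
        dist: DegreeDistribution = connectivity
        if not isinstance(init, HeterogeneousState):
            raise ParameterError("heterogeneous integration needs a HeterogeneousState init")
        m = dist.degrees.size
        y0 = np.concatenate([init.Sk, init.Ik, init.Rk, [0.0] if snes else []])
        k = dist.degrees.astype(np.float64)
        kp_over_km = dist.degrees * dist.probs / dist.mean_degree

        def rhs(t, y):
            Sk, Ik, Rk = y[:m], y[m : 2 * m], y[2 * m : 3 * m]
            theta = float(kp_over_km @ Ik)
            infect = params.beta_eff * k * Sk * theta
            recover = params.gamma_eff * Ik
            inflow = params.b * params.N
            dSk = -params.d * Sk - infect
            dIk = infect - recover - params.d * Ik
            dRk = recover - params.d * Rk
            if snes:
                dP = inflow - params.d * y[3 * m]
                return np.concatenate([dSk, dIk, dRk, [dP]])
            return np.concatenate([dSk + inflow, dIk, dRk])

    else:
        k_mean = float(connectivity)
        if k_mean <= 0:
            raise ParameterError(f"mean degree must be > 0, got {k_mean}")
        init = np.asarray(init, dtype=np.float64)
        if init.size != 3:
            raise ParameterError("homogeneous init must be (S0, I0, R0)")
        y0 = np.concatenate([init, [0.0]]) if snes else init.copy()

        def rhs(t, y):
            infect = params.beta_eff * k_mean * y[0] * y[1]
            recover = params.gamma_eff * y[1]
            inflow = params.b * params.N
            dS = -params.d * y[0] - infect
            dI = infect - recover - params.d * y[1]
            dR = recover - params.d * y[2]
            if snes:
                return np.array([dS, dI, dR, inflow - params.d * y[3]])
            return np.array([dS + inflow, dI, dR])

    if np.any(np.asarray(y0) < 0):
        raise ParameterError("initial state must be non-negative")

    grid = config.grid
    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        y0,
        t_eval=grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(
            f"mean-field integration failed at t={sol.t[-1] if sol.t.size else grid[0]}: "
            f"{sol.message}"
        )

    if heterogeneous:
        m = dist.degrees.size
        p = dist.probs
        S = p @ sol.y[:m]
        I = p @ sol.y[m : 2 * m]
        R = p @ sol.y[2 * m : 3 * m]
        if snes:
            S = S + sol.y[3 * m]
    else:
        S, I, R = sol.y[0], sol.y[1], sol.y[2]
        if snes:
            S = S + sol.y[3]
    return Trajectory(times=sol.t, S=S, I=I, R=R, mode="density")


def total_population_closed_form(params: EpidemicParams, T0: float, t) -> np.ndarray:
    """Total population T(t) solving dT/dt = b N - d T.

    ``b N / d + (T0 - b N / d) exp(-d t)`` for d > 0, the linear branch
    ``T0 + b N t`` for d = 0. Serves as an analytic oracle for the
    integrator's conservation law.
    """
    t = np.asarray(t, dtype=np.float64)
    inflow = params.b * params.N
    if params.d == 0:
        return T0 + inflow * t
    t_inf = inflow / params.d
    return t_inf + (T0 - t_inf) * np.exp(-params.d * t)
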