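"""Shared domain types: epidemic rates, degree distributions, trajectories.

The model couples a standard network SIR (or SIS) contagion with two
immunization channels — vaccination, which scales the per-contact infection
rate by ``(1 - delta)`` for every susceptible, and clinical treatment, which
scales the recovery rate by ``(1 + lambda)`` for every infected — plus simple
demography: a constant inflow of susceptibles at rate ``b*N`` and a natural
(non-disease) per-capita death rate ``d`` applied to every compartment.

Network structure enters only through the degree distribution ``p(k)``:
homogeneous formulations use the mean degree ``<k>``, heterogeneous ones the
ratio ``<k^2>/<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EpidemicParams",
    "DegreeDistribution",
    "Trajectory",
    "EquilibriumPoint",
    "SimulationConfig",
    "ParameterError",
    "validate_params",
    "poisson_degree_distribution",
    "empirical_degree_distribution",
    "degenerate_distribution",
]


class ParameterError(ValueError):
    """A model parameter is outside its valid domain."""


@dataclass(frozen=True)
class EpidemicParams:
    """The six model rates plus the population scale N.

    Attributes
    ----------
    b : float
        Birth rate (inflow of susceptibles as a fraction of N per unit time).
    d : float
        Natural death rate per capita per unit time; identical across
        compartments and not disease-induced.
    beta : float
        Per-contact infection rate per unit time.
    gamma : float
        Baseline recovery rate per unit time.
    delta : float
        Vaccination-derived reduction of the infection rate, in [0, 1];
        the effective per-contact rate is ``beta * (1 - delta)``.
    lam : float
        Treatment-derived enhancement of the recovery rate (>= 0); the
        effective recovery rate is ``gamma * (1 + lam)``.
    N : float
        Population scale: 1 for density formulations, an integer >= 2 for
        count (CTMC / network) formulations.
    """

    b: float
    d: float
    beta: float
    gamma: float
    delta: float
    lam: float
    N: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b", "d", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.delta <= 1.0:
            raise ParameterError(f"delta must lie in [0, 1], got {self.delta}")
        if self.lam < 0:
            raise ParameterError(f"lam must be >= 0, got {self.lam}")
        if self.N <= 0:
            raise ParameterError(f"N must be > 0, got {self.N}")

    @property
    def beta_eff(self) -> float:
        """Effective per-contact infection rate ``beta * (1 - delta)``."""
        return self.beta * (1.0 - self.delta)

    @property
    def gamma_eff(self) -> float:
        """Effective recovery rate ``gamma * (1 + lam)``."""
        return self.gamma * (1.0 + self.lam)

    def replace(self, **changes) -> "EpidemicParams":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def validate_params(
    b: float,
    d: float,
    beta: float,
    gamma: float,
    delta: float,
    lam: float,
    N: float = 1.0,
) -> EpidemicParams:
    """Validate raw rate values and return an :class:`EpidemicParams`.

    Raises :class:`ParameterError` naming the offending field if any value is
    outside its domain; values are passed through unchanged otherwise.
    """
    return EpidemicParams(b=b, d=d, beta=beta, gamma=gamma, delta=delta, lam=lam, N=N)


@dataclass(frozen=True)
class DegreeDistribution:
    """Finite-support degree distribution with cached moments.

    ``degrees`` is strictly increasing, ``probs`` sums to one. The two
    moments ``<k>`` and ``<k^2>`` are what every analytic formula consumes;
    the ratio ``<k^2>/<k>`` is the heterogeneous connectivity factor.
    """

    degrees: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        degrees = np.asarray(self.degrees, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "degrees", degrees)
        object.__setattr__(self, "probs", probs)
        if degrees.ndim != 1 or probs.ndim != 1 or degrees.size != probs.size:
            raise ParameterError("degrees and probs must be 1-D and of equal length")
        if degrees.size == 0:
            raise ParameterError("degree support must be non-empty")
        if np.any(degrees < 0):
            raise ParameterError("degrees must be non-negative")
        if np.any(np.diff(degrees) <= 0):
            raise ParameterError("degrees must be strictly increasing")
        if np.any(probs < 0):
            raise ParameterError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ParameterError(f"probabilities must sum to 1, got {probs.sum()!r}")

    @property
    def mean_degree(self) -> float:
        """First moment ``<k>``."""
        return float(np.dot(self.degrees, self.probs))

    @property
    def second_moment(self) -> float:
        """Second moment ``<k^2>``."""
        return float(np.dot(self.degrees.astype(np.float64) ** 2, self.probs))

    @property
    def connectivity_ratio(self) -> float:
        """Heterogeneous connectivity factor ``<k^2>/<k>``."""
        km = self.mean_degree
        if km == 0:
            raise ParameterError("mean degree is zero; connectivity ratio undefined")
        return self.second_moment / km


def poisson_degree_distribution(xi: float, k_max: int) -> DegreeDistribution:
    """Truncated-and-renormalized Poisson degree distribution.

    The homogeneous (Erdos-Renyi-like) case: ``p(k) ~ xi^k e^-xi / k!`` over
    ``k = 0..k_max``. ``k_max`` must capture at least ``1 - 1e-9`` of the
    Poisson mass so the truncation is numerically invisible.
    """
    if xi <= 0:
        raise ParameterError(f"xi must be > 0, got {xi}")
    k = np.arange(int(k_max) + 1)
    pmf = stats.poisson.pmf(k, xi)
    mass = pmf.sum()
    if mass < 1.0 - 1e-9:
        raise ParameterError(
            f"k_max={k_max} captures only {mass:.6g} of the Poisson({xi}) mass; "
            "increase k_max"
        )
    return DegreeDistribution(degrees=k, probs=pmf / mass)


def empirical_degree_distribution(network) -> DegreeDistribution:
    """Observed degree frequencies of a contact network.

    Accepts a :class:`bisir.netsim.ContactNetwork` or a ``networkx.Graph``.
    """
    degs = _degree_sequence(network)
    if degs.size == 0:
        raise ParameterError("network has no nodes")
    counts = np.bincount(degs)
    support = np.nonzero(counts)[0]
    return DegreeDistribution(degrees=support, probs=counts[support] / degs.size)


def _degree_sequence(network) -> np.ndarray:
    graph = getattr(network, "graph", network)
    try:
        return np.array([d for _, d in graph.degree()], dtype=np.int64)
    except AttributeError as exc:  # pragma: no cover - defensive
        raise TypeError(f"cannot extract degrees from {type(network)!r}") from exc


def degenerate_distribution(k: int) -> DegreeDistribution:
    """Point mass at degree ``k``: the homogeneous limit ``<k^2>/<k> = k``."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    return DegreeDistribution(degrees=np.array([int(k)]), probs=np.array([1.0]))


@dataclass
class Trajectory:
    """Time series of the three compartments.

    ``mode`` is ``"density"`` (mean-field, ensemble averages) or ``"count"``
    (single stochastic runs). All component arrays share the time grid.
    """

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    mode: Literal["density", "count"] = "density"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        self.R = np.asarray(self.R, dtype=np.float64)
        n = self.times.size
        if not (self.S.size == self.I.size == self.R.size == n):
            raise ParameterError("trajectory arrays must share one length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.mode not in ("density", "count"):
            raise ParameterError(f"unknown trajectory mode {self.mode!r}")

    @property
    def total(self) -> np.ndarray:
        return self.S + self.I + self.R


@dataclass(frozen=True)
class EquilibriumPoint:
    """A stationary point of the degree-structured mean-field system.

    ``Sk``, ``Ik``, ``Rk`` are per-degree-class values aligned with a
    :class:`DegreeDistribution` support (length-1 arrays in the scalar,
    homogeneous case); ``theta`` is the infected-edge fraction at the point.
    """

    kind: Literal["disease_free", "endemic"]
    Sk: np.ndarray
    Ik: np.ndarray
    Rk: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "Sk", np.atleast_1d(np.asarray(self.Sk, dtype=float)))
        object.__setattr__(self, "Ik", np.atleast_1d(np.asarray(self.Ik, dtype=float)))
        object.__setattr__(self, "Rk", np.atleast_1d(np.asarray(self.Rk, dtype=float)))
        if self.kind == "disease_free":
            if self.theta != 0 or np.any(self.Ik != 0):
                raise ParameterError("disease-free point must have Ik = 0 and theta = 0")
        if np.any(self.Sk < 0) or np.any(self.Ik < 0) or np.any(self.Rk < 0):
            raise ParameterError("equilibrium components must be non-negative")


NewbornMode = Literal["SPES", "SNES"]
ModelVariant = Literal["SIR", "SIR_star", "SIS", "SIS_star"]


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration shared by the integrator and the simulators.

    ``newborn_mode`` selects whether newborn susceptibles participate in
    spreading (SPES) or accumulate in a passive, non-transmitting pool
    (SNES). ``model_variant`` picks plain SIR/SIS (immunization off) or the
    starred variants with both immunization channels active.
    """

    t_max: float
    dt: float = 1.0
    replicates: int = 1
    seed: int = 0
    newborn_mode: NewbornMode = "SPES"
    model_variant: ModelVariant = "SIR_star"

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ParameterError(f"t_max must be > 0, got {self.t_max}")
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.replicates < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates}")
        if self.newborn_mode not in ("SPES", "SNES"):
            raise ParameterError(f"unknown newborn_mode {self.newborn_mode!r}")
        if self.model_variant not in ("SIR", "SIR_star", "SIS", "SIS_star"):
            raise ParameterError(f"unknown model_variant {self.model_variant!r}")

    @property
    def grid(self) -> np.ndarray:
        """Uniform reporting grid ``0, dt, 2 dt, ..., <= t_max``."""
        n = int(np.floor(self.t_max / self.dt + 1e-9))
        return np.linspace(0.0, n * self.dt, n + 1)
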