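"""Continuous-time Markov-chain layer: a birth-death chain on infected counts.

The stochastic counterpart of the mean-field model is a CTMC on the pair
(s, i) of susceptible and infected counts with exactly two event types:

    infection  (s, i) -> (s-1, i+1)  at rate  rho(s, i) = (s/N) beta i (1-delta) C
    recovery   (s, i) -> (s, i-1)    at rate  mu(s, i)  = gamma i (1+lam)

where C is the connectivity factor (<k> homogeneous, <k^2>/<k>
heterogeneous). Births and deaths do not enter the chain: it is two-event
by construction.

Two boundary conventions coexist. The matrix artifacts (P, Q, pi, the
embedded chain) use the REFLECTED chain on i in {1..N} in which the
susceptible argument of rho follows the printed indexing rho(s0-i+1, i) —
s0 is the initial susceptible count, decremented once per infection already
booked — and state i=1 has no recovery exit. The Gillespie simulator uses
the ABSORBING chain with live (s, i) bookkeeping: i=0 ends the epidemic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import EpidemicParams, ParameterError, Trajectory

__all__ = [
    "CTMCState",
    "ChainSpec",
    "JumpTrajectory",
    "infection_rate",
    "recovery_rate",
    "transition_probability_matrix",
    "generator_matrix",
    "stationary_distribution",
    "stationary_distribution_closed_form",
    "embedded_chain_matrix",
    "gillespie_run",
    "ensemble_average",
]


@dataclass(frozen=True)
class CTMCState:
    """Susceptible/infected count pair; s + i never exceeds N."""

    s: int
    i: int

    def __post_init__(self) -> None:
        if self.s < 0 or self.i < 0:
            raise ParameterError("counts must be non-negative")


@dataclass(frozen=True)
class ChainSpec:
    """Finite birth-death chain specification over infected counts 1..N.

    ``connectivity`` is the single scalar through which network structure
    enters: <k> for a homogeneous chain, <k^2>/<k> for a heterogeneous one.
    ``boundary`` declares which convention an operation may assume.
    """

    N: int
    s0: int
    connectivity: float
    params: EpidemicParams
    boundary: Literal["reflected", "absorbing"] = "reflected"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"N must be an integer >= 2, got {self.N}")
        if not 1 <= self.s0 <= self.N - 1:
            raise ParameterError(f"s0 must lie in [1, N-1], got {self.s0}")
        if self.connectivity <= 0:
            raise ParameterError(f"connectivity must be > 0, got {self.connectivity}")
        if self.boundary not in ("reflected", "absorbing"):
            raise ParameterError(f"unknown boundary {self.boundary!r}")


@dataclass
class JumpTrajectory:
    """Event-time record of one stochastic run.

    ``states[j]`` holds between ``jump_times[j]`` and ``jump_times[j+1]``;
    consecutive states differ by one infection or one recovery. ``absorbed``
    marks termination at i = 0.
    """

    jump_times: np.ndarray
    states: list
    absorbed: bool

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        s = np.array([st.s for st in self.states], dtype=np.int64)
        i = np.array([st.i for st in self.states], dtype=np.int64)
        return s, i


def infection_rate(spec: ChainSpec, s: int, i: int) -> float:
    """rho(s, i) = (s/N) beta i (1-delta) C; zero when s = 0 or i = 0."""
    if s < 0 or i < 0 or s + i > spec.N:
        raise ParameterError(f"invalid state (s={s}, i={i}) for N={spec.N}")
    p = spec.params
    return (s / spec.N) * p.beta * i * (1.0 - p.delta) * spec.connectivity


def recovery_rate(spec: ChainSpec, i: int) -> float:
    """mu(i) = gamma i (1+lam); the susceptible count does not enter."""
    if i < 0:
        raise ParameterError(f"i must be >= 0, got {i}")
    p = spec.params
    return p.gamma * i * (1.0 + p.lam)


def _reflected_rates(spec: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """(rho_i, mu_i) for i = 1..N under the printed reflected indexing.

    rho_i = rho(s0 - i + 1, i) with a floor of zero susceptibles;
    mu_i = mu(s0, i) = gamma i (1+lam).
    """
    i = np.arange(1, spec.N + 1)
    s_arg = np.maximum(spec.s0 - i + 1, 0)
    p = spec.params
    rho = (s_arg / spec.N) * p.beta * i * (1.0 - p.delta) * spec.connectivity
    mu = p.gamma * i * (1.0 + p.lam)
    return rho.astype(np.float64), mu.astype(np.float64)


def transition_probability_matrix(spec: ChainSpec, dt: float) -> np.ndarray:
    """First-order transition matrix P over i = 1..N for one step of length dt.

    Superdiagonal rho(s0-i+1, i) dt, subdiagonal mu(i) dt (absent in row 1:
    the printed chain reflects at i=1), diagonal completing each row to 1.
    dt must keep every row inside [0, 1].
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    rho, mu = _reflected_rates(spec)
    exit_rates = rho.copy()
    exit_rates[1:] += mu[1:]  # row 1 has no recovery exit
    exit_rates[-1] = mu[-1]  # row N has no infection exit (rho vanishes there)
    max_rate = float(exit_rates.max())
    if dt * max_rate > 1.0:
        raise ParameterError(
            f"dt={dt} too large for first-order probabilities; "
            f"need dt <= {1.0 / max_rate:.6g}"
        )
    n = spec.N
    P = np.zeros((n, n))
    for row, i in enumerate(range(1, n + 1)):
        if i < n:
            P[row, row + 1] = rho[row] * dt
        if i > 1:
            P[row, row - 1] = mu[row] * dt
        P[row, row] = 1.0 - P[row].sum()
    return P


def generator_matrix(spec: ChainSpec) -> np.ndarray:
    """Transition-rate matrix Q of the reflected chain; rows sum to zero."""
    rho, mu = _reflected_rates(spec)
    n = spec.N
    Q = np.zeros((n, n))
    for row, i in enumerate(range(1, n + 1)):
        if i < n:
            Q[row, row + 1] = rho[row]
        if i > 1:
            Q[row, row - 1] = mu[row]
        Q[row, row] = -Q[row].sum()
    return Q


def stationary_distribution(spec: ChainSpec) -> np.ndarray:
    """Stationary distribution pi over i = 1..N of the reflected chain.

    Detailed balance of the birth-death structure gives the recursion
    pi_{i+1} / pi_i = rho(s0-i+1, i) / mu(i+1); accumulated in log space
    and normalized. States unreachable once the susceptible argument hits
    zero carry exactly zero mass.
    """
    if spec.boundary != "reflected":
        raise ParameterError("stationary distribution requires the reflected chain")
    p = spec.params
    if p.gamma * (1.0 + p.lam) <= 0:
        raise ParameterError("gamma (1+lam) must be > 0 for the stationary recursion")
    rho, mu = _reflected_rates(spec)
    log_pi = np.full(spec.N, -np.inf)
    log_pi[0] = 0.0
    for idx in range(spec.N - 1):
        if rho[idx] <= 0:
            break
        log_pi[idx + 1] = log_pi[idx] + np.log(rho[idx]) - np.log(mu[idx + 1])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi[np.isneginf(log_pi)] = 0.0
    return pi / pi.sum()


def stationary_distribution_closed_form(spec: ChainSpec) -> np.ndarray:
    """Closed-form pi_i ~ s0! / (i (s0-i+1)!) * (beta (1-delta) C / (N gamma (1+lam)))^(i-1).

    Product form of the recursion; used as an independent cross-check of
    :func:`stationary_distribution`. Computed in log space via lgamma.
    """
    from math import lgamma, log

    p = spec.params
    if p.gamma * (1.0 + p.lam) <= 0:
        raise ParameterError("gamma (1+lam) must be > 0")
    x = p.beta * (1.0 - p.delta) * spec.connectivity / (spec.N * p.gamma * (1.0 + p.lam))
    log_pi = np.full(spec.N, -np.inf)
    for idx, i in enumerate(range(1, spec.N + 1)):
        if i - 1 > spec.s0:  # ran out of susceptibles; unreachable
            break
        if x == 0 and i > 1:
            break
        term = lgamma(spec.s0 + 1) - lgamma(spec.s0 - i + 2) - log(i)
        if i > 1:
            term += (i - 1) * log(x)
        log_pi[idx] = term
    finite = np.isfinite(log_pi)
    log_pi[finite] -= log_pi[finite].max()
    pi = np.exp(log_pi)
    pi[~finite] = 0.0
    return pi / pi.sum()


def embedded_chain_matrix(spec: ChainSpec) -> np.ndarray:
    """Jump-destination probabilities of the reflected chain.

    Zero diagonal; interior row i splits exits as mu/(rho+mu) down and
    rho/(rho+mu) up; boundary rows jump deterministically (row 1 up, row N
    down). Errors if some state has no exit at all.
    """
    rho, mu = _reflected_rates(spec)
    n = spec.N
    R = np.zeros((n, n))
    for row, i in enumerate(range(1, n + 1)):
        if i == 1:
            if rho[row] <= 0:
                raise ParameterError(f"state i={i} has zero exit rate")
            R[row, row + 1] = 1.0
        elif i == n:
            if mu[row] <= 0:
                raise ParameterError(f"state i={i} has zero exit rate")
            R[row, row - 1] = 1.0
        else:
            total = rho[row] + mu[row]
            if total <= 0:
                raise ParameterError(f"state i={i} has zero exit rate")
            R[row, row - 1] = mu[row] / total
            R[row, row + 1] = rho[row] / total
    return R


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """One named stream per replicate: reproducible under parallel fan-out."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, replicate))))


def gillespie_run(
    spec: ChainSpec,
    i0: int,
    t_max: float,
    seed: int,
    replicate: int = 0,
) -> JumpTrajectory:
    """Exact stochastic simulation of the absorbing chain.

    At live state (s, i): waiting time ~ Exponential(rho + mu), the event is
    an infection with probability rho/(rho+mu). Stops at t_max, at i = 0
    (absorbed), or when both rates vanish. Bit-reproducible given
    (seed, replicate).
    """
    if spec.boundary != "absorbing":
        raise ParameterError("gillespie_run requires an absorbing-boundary spec")
    if i0 < 1:
        raise ParameterError(f"i0 must be >= 1, got {i0}")
    if i0 + spec.s0 > spec.N:
        raise ParameterError("i0 + s0 exceeds N")
    rng = _replicate_rng(seed, replicate)
    p = spec.params
    s, i = spec.s0, i0
    t = 0.0
    times = [0.0]
    states = [CTMCState(s, i)]
    absorbed = False
    while True:
        rho = (s / spec.N) * p.beta * i * (1.0 - p.delta) * spec.connectivity
        mu = p.gamma * i * (1.0 + p.lam)
        total = rho + mu
        if total <= 0:
            absorbed = i == 0
            break
        # inverse-transform exponential draw
        t = t + -np.log(rng.random()) / total
        if t > t_max:
            break
        if rng.random() < rho / total:
            s, i = s - 1, i + 1
        else:
            i = i - 1
        times.append(t)
        states.append(CTMCState(s, i))
        if i == 0:
            absorbed = True
            break
    return JumpTrajectory(jump_times=np.asarray(times), states=states, absorbed=absorbed)


def ensemble_average(
    runs: Sequence[JumpTrajectory],
    grid: Sequence[float],
    N: int,
) -> Trajectory:
    """Replicate-mean densities on a common grid (last state carried forward).

    The chain has no births or deaths, so r = (s0 + i0) - s - i recovers the
    recovered count; densities are counts over N.
    """
    if len(runs) == 0:
        raise ParameterError("need at least one run to average")
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or (grid.size > 1 and np.any(np.diff(grid) <= 0)):
        raise ParameterError("grid must be 1-D and strictly increasing")
    S = np.zeros(grid.size)
    I = np.zeros(grid.size)
    for run in runs:
        s, i = run.counts()
        idx = np.searchsorted(run.jump_times, grid, side="right") - 1
        idx = np.clip(idx, 0, len(s) - 1)
        S += s[idx]
        I += i[idx]
    S /= len(runs) * N
    I /= len(runs) * N
    total0 = (runs[0].states[0].s + runs[0].states[0].i) / N
    R = total0 - S - I
    return Trajectory(times=grid, S=S, I=I, R=np.maximum(R, 0.0), mode="density")
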