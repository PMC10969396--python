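"""Discrete-time Monte-Carlo contagion on explicit contact networks.

Synchronous per-step updates on an undirected simple graph:

* each susceptible node with ``m`` infected living neighbours becomes
  infected with probability ``1 - (1 - beta (1-delta))**m`` (independent
  per-neighbour transmission);
* each infected node recovers with probability ``min(1, gamma (1+lam))``,
  moving to R (SIR variants) or back to S (SIS variants);
* each living node dies with probability ``min(1, d)`` per step (natural
  death; dead nodes drop out of transmission, which is equivalent to
  deleting their edges);
* ``round(b * n)`` newborn susceptibles join a passive, non-transmitting
  pool each step (the SNES convention) and are themselves subject to the
  death probability; densities are normalized by the initial node count.

Plain ``SIR``/``SIS`` variants force delta = lam = 0; the starred variants
apply the bidirectional immunization. All randomness flows through one
generator per replicate; the three per-node uniform arrays (infection,
recovery, death) are drawn every step in a fixed order, so two variants run
with the same seed consume identical random streams and can be coupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .core import EpidemicParams, ParameterError, SimulationConfig, Trajectory

__all__ = [
    "ContactNetwork",
    "MCSResult",
    "generate_er",
    "generate_ba",
    "mcs_run",
    "replicate_average",
    "epidemic_metrics",
    "immunization_sweep",
]


@dataclass
class ContactNetwork:
    """Undirected simple graph with node ids 0..n-1.

    Thin wrapper over a ``networkx.Graph`` caching the CSR adjacency used
    by the simulator.
    """

    graph: nx.Graph
    _adjacency: Optional[sparse.csr_matrix] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.graph.number_of_nodes()
        if n == 0:
            raise ParameterError("network must have at least one node")
        if set(self.graph.nodes()) != set(range(n)):
            raise ParameterError("node ids must be 0..n-1; relabel before wrapping")
        if any(u == v for u, v in self.graph.edges()):
            raise ParameterError("self-loops are not allowed")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> sparse.csr_matrix:
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self.graph, nodelist=range(self.n), dtype=np.float64, format="csr"
            )
        return self._adjacency

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "ContactNetwork":
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(graph=g)


@dataclass
class MCSResult:
    """Replicate-averaged trajectory plus per-replicate summary metrics."""

    trajectory: Trajectory
    peak_I: np.ndarray  # per replicate
    final_S: np.ndarray
    final_I: np.ndarray
    final_R: np.ndarray
    passive: np.ndarray  # mean passive-pool density per step
    states: Optional[list] = None  # per-step status snapshots, single runs only

    @property
    def n_replicates(self) -> int:
        return self.peak_I.size


def generate_er(n: int, mean_degree: float, seed: int) -> ContactNetwork:
    """Erdos-Renyi G(n, p) with p = mean_degree / (n - 1); seed-reproducible."""
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    p = mean_degree / (n - 1)
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"mean_degree={mean_degree} gives invalid p={p}")
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    return ContactNetwork(graph=g)


def generate_ba(n: int, m: int, seed: int) -> ContactNetwork:
    """Barabasi-Albert preferential attachment; mean degree ~ 2m for large n."""
    if m < 1 or m >= n:
        raise ParameterError(f"need 1 <= m < n, got m={m}, n={n}")
    g = nx.barabasi_albert_graph(n, m, seed=int(seed))
    return ContactNetwork(graph=g)


_S, _I, _R, _DEAD = 0, 1, 2, 3


def _effective_rates(params: EpidemicParams, variant: str) -> tuple[float, float]:
    if variant in ("SIR", "SIS"):
        return params.beta, min(1.0, params.gamma)
    if variant in ("SIR_star", "SIS_star"):
        return params.beta_eff, min(1.0, params.gamma_eff)
    raise ParameterError(f"unknown model_variant {variant!r}")


def mcs_run(
    network: ContactNetwork,
    params: EpidemicParams,
    config: SimulationConfig,
    initial_infected: Union[int, Sequence[int]] = 1,
    seed: int = 0,
    replicate: int = 0,
    record_states: bool = False,
) -> MCSResult:
    """One synchronous-update replicate on a fixed network.

    ``initial_infected`` is either a count (nodes chosen uniformly) or an
    explicit node set. One step corresponds to one unit of time; the run
    covers ``int(t_max)`` steps. Returns a density-mode result normalized
    by the initial node count.
    """
    beta_eff, rec_prob = _effective_rates(params, config.model_variant)
    sis = config.model_variant in ("SIS", "SIS_star")
    death_prob = min(1.0, params.d)
    births_per_step = int(round(params.b * network.n))

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, replicate))))
    n = network.n
    A = network.adjacency()

    status = np.full(n, _S, dtype=np.int8)
    if np.isscalar(initial_infected):
        count = int(initial_infected)
        if not 1 <= count <= n:
            raise ParameterError(f"initial infected count {count} outside [1, n]")
        seeds_nodes = rng.choice(n, size=count, replace=False)
    else:
        seeds_nodes = np.asarray(list(initial_infected), dtype=np.int64)
        if seeds_nodes.size == 0 or np.any(seeds_nodes < 0) or np.any(seeds_nodes >= n):
            raise ParameterError("initial_infected nodes outside the network")
    status[seeds_nodes] = _I

    n_steps = int(config.t_max)
    S_d = np.empty(n_steps + 1)
    I_d = np.empty(n_steps + 1)
    R_d = np.empty(n_steps + 1)
    P_d = np.empty(n_steps + 1)
    passive = 0.0
    snapshots: Optional[list] = [] if record_states else None

    def record(step: int) -> None:
        S_d[step] = ((status == _S).sum() + passive) / n
        I_d[step] = (status == _I).sum() / n
        R_d[step] = (status == _R).sum() / n
        P_d[step] = passive / n
        if snapshots is not None:
            snapshots.append(status.copy())

    record(0)
    log1m = np.log1p(-beta_eff) if beta_eff < 1.0 else -np.inf

    for step in range(1, n_steps + 1):
        # fixed draw order -> identical streams across variants (coupling)
        u_inf = rng.random(n)
        u_rec = rng.random(n)
        u_death = rng.random(n)

        infected = status == _I
        susceptible = status == _S
        if infected.any():
            m_inf = A @ infected.astype(np.float64)
            # 1 - (1 - beta_eff)^m, computed stably
            p_inf = -np.expm1(m_inf * log1m) if np.isfinite(log1m) else (m_inf > 0) * 1.0
            new_inf = susceptible & (u_inf < p_inf)
        else:
            new_inf = np.zeros(n, dtype=bool)
        new_rec = infected & (u_rec < rec_prob)

        status[new_inf] = _I
        status[new_rec] = _S if sis else _R

        if death_prob > 0:
            dying = (status != _DEAD) & (u_death < death_prob)
            status[dying] = _DEAD
            if passive > 0:
                passive -= rng.binomial(int(passive), death_prob)
        passive += births_per_step
        record(step)

    times = np.arange(n_steps + 1, dtype=np.float64)
    traj = Trajectory(times=times, S=S_d, I=I_d, R=R_d, mode="density")
    tail = max(1, int(np.ceil(0.1 * (n_steps + 1))))
    return MCSResult(
        trajectory=traj,
        peak_I=np.array([I_d.max()]),
        final_S=np.array([S_d[-tail:].mean()]),
        final_I=np.array([I_d[-tail:].mean()]),
        final_R=np.array([R_d[-tail:].mean()]),
        passive=P_d,
        states=snapshots,
    )


def replicate_average(
    network: Union[ContactNetwork, Callable[[int], ContactNetwork]],
    params: EpidemicParams,
    config: SimulationConfig,
    n_reps: int,
    base_seed: int,
    initial_infected: Union[int, Sequence[int]] = 1,
) -> MCSResult:
    """Average ``n_reps`` independent replicates.

    ``network`` may be a fixed :class:`ContactNetwork` or a factory
    ``seed -> ContactNetwork`` drawing a fresh graph per replicate.
    Replicate r uses the random stream (base_seed, r); the whole call is
    deterministic given its arguments.
    """
    if n_reps < 1:
        raise ParameterError(f"n_reps must be >= 1, got {n_reps}")
    factory = network if callable(network) else (lambda _s: network)

    traj_S = traj_I = traj_R = traj_P = None
    peaks, fS, fI, fR = [], [], [], []
    times = None
    for r in range(n_reps):
        net = factory(base_seed + r)
        res = mcs_run(net, params, config, initial_infected, seed=base_seed, replicate=r)
        t = res.trajectory
        if traj_S is None:
            traj_S, traj_I, traj_R = t.S.copy(), t.I.copy(), t.R.copy()
            traj_P = res.passive.copy()
            times = t.times
        else:
            traj_S += t.S
            traj_I += t.I
            traj_R += t.R
            traj_P += res.passive
        peaks.append(res.peak_I[0])
        fS.append(res.final_S[0])
        fI.append(res.final_I[0])
        fR.append(res.final_R[0])
    traj = Trajectory(
        times=times, S=traj_S / n_reps, I=traj_I / n_reps, R=traj_R / n_reps, mode="density"
    )
    return MCSResult(
        trajectory=traj,
        peak_I=np.asarray(peaks),
        final_S=np.asarray(fS),
        final_I=np.asarray(fI),
        final_R=np.asarray(fR),
        passive=traj_P / n_reps,
    )


def epidemic_metrics(result: MCSResult) -> dict:
    """Peak and steady-state summaries of the replicate-mean trajectory.

    Returns peak_I and t_peak from the mean trajectory, and I_inf / R_inf /
    S_inf as means over the final 10% of steps.
    """
    t = result.trajectory
    if t.times.size == 0:
        raise ParameterError("empty trajectory")
    tail = max(1, int(np.ceil(0.1 * t.times.size)))
    peak_idx = int(np.argmax(t.I))
    return {
        "peak_I": float(t.I[peak_idx]),
        "t_peak": float(t.times[peak_idx]),
        "I_inf": float(t.I[-tail:].mean()),
        "R_inf": float(t.R[-tail:].mean()),
        "S_inf": float(t.S[-tail:].mean()),
    }


def immunization_sweep(
    network: Union[ContactNetwork, Callable[[int], ContactNetwork]],
    params: EpidemicParams,
    delta_grid: Sequence[float],
    beta_grid: Sequence[float],
    config: SimulationConfig,
    n_reps: int,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Steady-state R and S densities over a (delta, beta) grid.

    One row per pair with replicate-averaged ``R_inf`` and ``S_inf``;
    lam and all other parameters held fixed.
    """
    rows = []
    for delta in delta_grid:
        for beta in beta_grid:
            p = params.replace(delta=float(delta), beta=float(beta))
            res = replicate_average(network, p, config, n_reps, base_seed)
            m = epidemic_metrics(res)
            rows.append(
                {
                    "delta": float(delta),
                    "beta": float(beta),
                    "R_inf": m["R_inf"],
                    "S_inf": m["S_inf"],
                }
            )
    return pd.DataFrame(rows)
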