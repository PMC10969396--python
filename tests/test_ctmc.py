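import numpy as np
import pytest
from scipy import linalg, stats

from bisir import validate_params
from bisir.core import ParameterError
from bisir.ctmc import (
    ChainSpec,
    embedded_chain_matrix,
    ensemble_average,
    generator_matrix,
    gillespie_run,
    infection_rate,
    recovery_rate,
    stationary_distribution,
    stationary_distribution_closed_form,
    transition_probability_matrix,
)


def small_spec(boundary="reflected"):
    """The two-state worked example: N=2, s0=1, beta=0.2, gamma=0.1."""
    p = validate_params(b=0, d=0, beta=0.2, gamma=0.1, delta=0.0, lam=0.0, N=2)
    return ChainSpec(N=2, s0=1, connectivity=1.0, params=p, boundary=boundary)


def random_spec(rng, boundary="reflected", max_n=100):
    n = int(rng.integers(2, max_n + 1))
    p = validate_params(
        b=0, d=0,
        beta=float(rng.uniform(0.01, 1.0)),
        gamma=float(rng.uniform(0.01, 1.0)),
        delta=float(rng.uniform(0.0, 0.9)),
        lam=float(rng.uniform(0.0, 2.0)),
        N=n,
    )
    s0 = int(rng.integers(1, n))
    conn = float(rng.uniform(1.0, 12.0))
    return ChainSpec(N=n, s0=s0, connectivity=conn, params=p, boundary=boundary)


class TestRates:
    def test_no_infection_without_infected_or_susceptible(self):
        spec = small_spec()
        assert infection_rate(spec, 1, 0) == 0
        assert infection_rate(spec, 0, 1) == 0

    def test_hand_value(self):
        assert infection_rate(small_spec(), 1, 1) == pytest.approx(0.1)

    def test_heterogeneous_connectivity_scales_linearly(self):
        spec = small_spec()
        hot = ChainSpec(N=2, s0=1, connectivity=5.0, params=spec.params, boundary="reflected")
        assert infection_rate(hot, 1, 1) == pytest.approx(5 * infection_rate(spec, 1, 1))

    @pytest.mark.parametrize("gamma,lam,i,expected", [(0.1, 0.0, 1, 0.1), (0.05, 0.3, 10, 0.65), (0.2, 0.0, 0, 0.0)])
    def test_recovery_rate(self, gamma, lam, i, expected):
        p = validate_params(b=0, d=0, beta=0.1, gamma=gamma, delta=0, lam=lam, N=50)
        spec = ChainSpec(N=50, s0=25, connectivity=4.0, params=p)
        assert recovery_rate(spec, i) == pytest.approx(expected)


class TestTransitionMatrix:
    def test_worked_example(self):
        P = transition_probability_matrix(small_spec(), dt=1.0)
        assert np.allclose(P, [[0.9, 0.1], [0.2, 0.8]])

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            spec = random_spec(rng)
            dt = 0.9 / _max_exit_rate(spec)
            P = transition_probability_matrix(spec, dt)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert P.min() >= 0 and P.max() <= 1

    def test_off_diagonals_linear_in_dt(self):
        spec = small_spec()
        P1 = transition_probability_matrix(spec, 1.0)
        P2 = transition_probability_matrix(spec, 0.5)
        off = ~np.eye(2, dtype=bool)
        assert np.allclose(P2[off], P1[off] / 2)

    def test_oversized_dt_rejected_with_bound(self):
        with pytest.raises(ParameterError, match="dt"):
            transition_probability_matrix(small_spec(), dt=100.0)


def _max_exit_rate(spec):
    Q = generator_matrix(spec)
    return float((-np.diag(Q)).max())


class TestGeneratorMatrix:
    def test_rows_sum_to_zero_and_sign_pattern(self, rng):
        for _ in range(20):
            spec = random_spec(rng)
            Q = generator_matrix(spec)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            assert np.all(np.diag(Q) <= 0)
            off = Q[~np.eye(spec.N, dtype=bool)]
            assert np.all(off >= 0)

    def test_finite_difference_identity_with_P(self, rng):
        for _ in range(10):
            spec = random_spec(rng, max_n=30)
            Q = generator_matrix(spec)
            dt = 0.7 / max(_max_exit_rate(spec), 1e-9)
            P = transition_probability_matrix(spec, dt)
            assert np.allclose((P - np.eye(spec.N)) / dt, Q, atol=1e-12)


class TestStationaryDistribution:
    def test_two_state_local_balance(self):
        pi = stationary_distribution(small_spec())
        assert np.allclose(pi, [2 / 3, 1 / 3])

    def test_triple_agreement_recursion_closed_form_nullspace(self, rng):
        for _ in range(25):
            spec = random_spec(rng, max_n=100)
            pi = stationary_distribution(spec)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)
            cf = stationary_distribution_closed_form(spec)
            assert np.allclose(pi, cf, atol=1e-10)
            ns = linalg.null_space(generator_matrix(spec).T)
            assert ns.shape[1] == 1
            v = ns[:, 0] / ns[:, 0].sum()
            assert np.allclose(pi, v, atol=1e-10)

    def test_detailed_balance(self, rng):
        from bisir.ctmc import _reflected_rates

        for _ in range(10):
            spec = random_spec(rng, max_n=60)
            pi = stationary_distribution(spec)
            rho, mu = _reflected_rates(spec)
            for i in range(spec.N - 1):
                assert pi[i + 1] * mu[i + 1] == pytest.approx(pi[i] * rho[i], abs=1e-12)

    def test_zero_recovery_rejected(self):
        p = validate_params(b=0, d=0, beta=0.2, gamma=0.0, delta=0, lam=0, N=5)
        spec = ChainSpec(N=5, s0=4, connectivity=1.0, params=p)
        with pytest.raises(ParameterError):
            stationary_distribution(spec)


class TestEmbeddedChain:
    def test_two_state_boundary_rows(self):
        R = embedded_chain_matrix(small_spec())
        assert np.allclose(R, [[0, 1], [1, 0]])

    def test_rows_sum_to_one_zero_diagonal(self, rng):
        for _ in range(15):
            spec = random_spec(rng, max_n=80)
            R = embedded_chain_matrix(spec)
            assert np.allclose(R.sum(axis=1), 1.0)
            assert np.all(np.diag(R) == 0)

    def test_equal_rates_split_evenly(self):
        # rho = mu at the interior state: beta*conn*(s/N) = gamma
        p = validate_params(b=0, d=0, beta=0.3, gamma=0.1, delta=0, lam=0, N=3)
        spec = ChainSpec(N=3, s0=2, connectivity=1.0, params=p)
        # state i=2: rho(1,2) = (1/3)*0.3*2 = 0.2, mu(2) = 0.2
        R = embedded_chain_matrix(spec)
        assert R[1, 0] == pytest.approx(0.5) and R[1, 2] == pytest.approx(0.5)

    def test_matches_normalized_generator_off_diagonals(self, rng):
        for _ in range(10):
            spec = random_spec(rng, max_n=50)
            Q = generator_matrix(spec)
            R = embedded_chain_matrix(spec)
            off = Q - np.diag(np.diag(Q))
            expected = off / off.sum(axis=1, keepdims=True)
            assert np.allclose(R, expected)


class TestGillespie:
    def test_recovery_only_jump_count(self):
        p = validate_params(b=0, d=0, beta=0.2, gamma=0.1, delta=1.0, lam=0.0, N=50)
        spec = ChainSpec(N=50, s0=40, connectivity=4.0, params=p, boundary="absorbing")
        run = gillespie_run(spec, i0=7, t_max=1e6, seed=3)
        assert run.absorbed
        assert run.jump_times.size - 1 == 7  # exactly i0 recoveries

    def test_reproducible_given_seed(self):
        p = validate_params(b=0, d=0, beta=0.4, gamma=0.1, delta=0.0, lam=0.0, N=100)
        spec = ChainSpec(N=100, s0=95, connectivity=4.0, params=p, boundary="absorbing")
        r1 = gillespie_run(spec, 5, 200.0, seed=9)
        r2 = gillespie_run(spec, 5, 200.0, seed=9)
        assert np.array_equal(r1.jump_times, r2.jump_times)
        assert r1.states == r2.states

    def test_no_recovery_consumes_all_susceptibles(self):
        p = validate_params(b=0, d=0, beta=5.0, gamma=0.0, delta=0.0, lam=0.0, N=30)
        spec = ChainSpec(N=30, s0=25, connectivity=4.0, params=p, boundary="absorbing")
        run = gillespie_run(spec, 5, 1e7, seed=1)
        s, i = run.counts()
        assert s[-1] == 0 and i[-1] == 30

    def test_reflected_spec_rejected(self):
        with pytest.raises(ParameterError):
            gillespie_run(small_spec("reflected"), 1, 10.0, seed=0)

    def test_single_infected_absorption_time_exponential(self):
        # delta=1: pure-death chain from i0=1, absorption ~ Exp(gamma(1+lam))
        rate = 0.05 * 1.3
        p = validate_params(b=0, d=0, beta=0.2, gamma=0.05, delta=1.0, lam=0.3, N=20)
        spec = ChainSpec(N=20, s0=10, connectivity=4.0, params=p, boundary="absorbing")
        times = np.array(
            [gillespie_run(spec, 1, 1e9, seed=77, replicate=r).jump_times[-1] for r in range(10_000)]
        )
        se = (1 / rate) / np.sqrt(times.size)
        assert abs(times.mean() - 1 / rate) < 3 * se
        ks = stats.kstest(times, stats.expon(scale=1 / rate).cdf)
        assert ks.pvalue > 0.01

    def test_pure_death_absorption_is_max_of_exponentials(self):
        # rate mu(i) = c*i: absorption from i0 = max of i0 iid Exp(c) lifetimes
        c, i0 = 0.1, 3
        p = validate_params(b=0, d=0, beta=0.2, gamma=0.1, delta=1.0, lam=0.0, N=20)
        spec = ChainSpec(N=20, s0=10, connectivity=4.0, params=p, boundary="absorbing")
        times = np.array(
            [gillespie_run(spec, i0, 1e9, seed=5, replicate=r).jump_times[-1] for r in range(10_000)]
        )
        cdf = lambda t: (1 - np.exp(-c * t)) ** i0
        ks = stats.kstest(times, cdf)
        assert ks.pvalue > 0.01


class TestEnsembleAverage:
    def test_single_run_recovered_exactly(self):
        p = validate_params(b=0, d=0, beta=0.4, gamma=0.1, delta=0.0, lam=0.0, N=50)
        spec = ChainSpec(N=50, s0=45, connectivity=4.0, params=p, boundary="absorbing")
        run = gillespie_run(spec, 5, 500.0, seed=2)
        traj = ensemble_average([run], run.jump_times, N=50)
        s, i = run.counts()
        assert np.allclose(traj.S * 50, s)
        assert np.allclose(traj.I * 50, i)

    def test_compartment_closure(self):
        p = validate_params(b=0, d=0, beta=0.4, gamma=0.1, delta=0.0, lam=0.0, N=50)
        spec = ChainSpec(N=50, s0=45, connectivity=4.0, params=p, boundary="absorbing")
        runs = [gillespie_run(spec, 5, 100.0, seed=4, replicate=r) for r in range(20)]
        traj = ensemble_average(runs, np.linspace(0, 100, 51), N=50)
        assert np.allclose(traj.total, 1.0, atol=1e-12)

    def test_empty_collection_rejected(self):
        with pytest.raises(ParameterError):
            ensemble_average([], [0.0, 1.0], N=10)
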