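"""Exactness of the simulation engines.

Oracles: closed-form exponential/Poisson laws for homogeneous systems,
hand-inverted cumulative hazards for time-dependent rates, and binomial
selection frequencies.
"""

import math

import numpy as np
import pytest
from scipy import stats

from ssan.engine import (
    RunawaySimulationError,
    SimulationConfig,
    cumulative_hazard,
    select_reaction,
    solve_jump_time,
    ssa_run,
    ssan_run,
)
from ssan.network import HybridState, Reaction, ReactionNetwork
from ssan.noise import NoiseChannel, NoiseRealization


def birth_death(kb=10.0, kd=1.0):
    return ReactionNetwork(
        ["X"],
        [Reaction("zeroth", kb, (), (1,)), Reaction("first", kd, (0,), (-1,))],
    )


def test_absorbing_state_terminates_without_events():
    net = ReactionNetwork(["X"], [Reaction("first", 1.0, (0,), (-1,))])
    tr = ssa_run(net, [0], SimulationConfig(T=5.0, rng_seed=0))
    assert tr.n_events == 0
    assert np.all(tr.species("X") == 0)


def test_pure_death_waiting_time_is_exponential():
    net = ReactionNetwork(["X"], [Reaction("first", 2.0, (0,), (-1,))])
    times = []
    for s in range(4000):
        tr = ssa_run(
            net, [1],
            SimulationConfig(T=50.0, rng_seed=s, record_grid=np.array([50.0]),
                             store_events=True),
        )
        times.append(tr.event_times[0])
    d = stats.kstest(times, stats.expon(scale=0.5).cdf)
    assert d.pvalue > 0.01


def test_record_grid_is_right_continuous_and_counts_piecewise_constant():
    net = birth_death()
    cfg = SimulationConfig(T=5.0, rng_seed=7, record_grid=np.linspace(0, 5, 51),
                           store_events=True)
    tr = ssa_run(net, [0], cfg)
    assert np.all(np.diff(tr.event_times) > 0)
    # value at t=0 is the initial state
    assert tr.counts[0, 0] == 0


def test_cumulative_hazard_constant_rate_is_linear():
    net = ReactionNetwork(["X"], [Reaction("zeroth", 3.0, (), (1,))])
    st = HybridState(np.array([0]), np.zeros(0), 0.0)
    lam = cumulative_hazard(net, st, [], 0.0, 2.5)
    assert lam[0] == pytest.approx(3.0 * 2.5)
    assert cumulative_hazard(net, st, [], 0.0, 0.0)[0] == 0.0


def test_cumulative_hazard_sinusoidal_matches_antiderivative():
    """With g(t) = 1 + eps sin(2 pi t / Tp) the hazard has a closed form."""
    eps, Tp, a = 0.5, 10.0, 2.0
    net = ReactionNetwork(["X"], [Reaction("zeroth", a, (), (1,), noise_channel=0)])
    ch = NoiseChannel("deterministic_periodic", amplitude=eps, tau=Tp,
                      granularity=Tp / 1000)
    real = NoiseRealization(ch, seed=0)
    st = HybridState(np.array([0]), np.zeros(1), 0.0)
    tau_c = 7.3
    lam = cumulative_hazard(net, st, [real], 0.0, tau_c)
    w = 2 * math.pi / Tp
    exact = a * (tau_c + eps * (1 - math.cos(w * tau_c)) / w)
    assert lam[0] == pytest.approx(exact, rel=1e-5)


def test_jump_time_degenerates_to_exponential_formula():
    net = birth_death(kb=4.0, kd=0.0)
    st = HybridState(np.array([0]), np.zeros(0), 0.0)
    r1 = 0.3777
    tau = solve_jump_time(net, st, [], 0.0, r1, T=1e6)
    assert tau == pytest.approx(math.log(1 / r1) / 4.0, rel=1e-10)


def test_jump_time_piecewise_constant_hazard_hand_inverted():
    """Rate 1 on [0,1), 3 afterwards; target ln(1/r1)=2 gives tau = 1 + 1/3."""

    def ratefn(counts, zeta, t):
        return 1.0 if t < 1.0 else 3.0

    net = ReactionNetwork(
        ["X"],
        [Reaction("generalized", stoich=(1,), propensity_fn=ratefn,
                  time_breakpoints=(1.0,))],
    )
    st = HybridState(np.array([0]), np.zeros(0), 0.0)
    tau = solve_jump_time(net, st, [], 0.0, math.exp(-2.0), T=100.0)
    assert tau == pytest.approx(4.0 / 3.0, abs=1e-8)


def test_jump_time_end_of_horizon_when_hazard_insufficient():
    net = birth_death(kb=0.01, kd=0.0)
    st = HybridState(np.array([0]), np.zeros(0), 0.0)
    assert solve_jump_time(net, st, [], 0.0, math.exp(-10.0), T=5.0) == math.inf
    net0 = ReactionNetwork(["X"], [Reaction("first", 1.0, (0,), (-1,))])
    st0 = HybridState(np.array([0]), np.zeros(0), 0.0)
    assert solve_jump_time(net0, st0, [], 0.0, 0.5, T=5.0) == math.inf


def test_reaction_selection_frequencies_and_exclusions():
    net = ReactionNetwork(
        ["X"],
        [Reaction("zeroth", 2.0, (), (1,)), Reaction("zeroth", 2.0, (), (1,)),
         Reaction("first", 5.0, (0,), (-1,))],  # zero propensity at X=0
    )
    st = HybridState(np.array([0]), np.zeros(0), 0.0)
    rng = np.random.default_rng(0)
    picks = np.array(
        [select_reaction(net, st, [], 0.0, rng.random()) for _ in range(4000)]
    )
    assert not np.any(picks == 2)
    k = int(np.sum(picks == 0))
    ci = stats.binomtest(k, 4000, 0.5).proportion_ci(0.999)
    assert ci.low <= 0.5 <= ci.high


def test_ssan_noise_free_matches_ssa_distribution():
    net = birth_death()
    cfg = lambda s: SimulationConfig(T=8.0, rng_seed=s, record_grid=np.array([8.0]))
    a = [ssa_run(net, [0], cfg(s)).final_counts[0] for s in range(1500)]
    b = [
        ssan_run(net, [0], [NoiseChannel("none")], cfg(10_000 + s)).final_counts[0]
        for s in range(1500)
    ]
    assert stats.ks_2samp(a, b).pvalue > 0.01


def test_ssan_zeroth_order_with_sine_wiener_keeps_mean_rate():
    """Cox process with zero-mean modulation: E[N(T)] = k*T."""
    net = ReactionNetwork(["X"], [Reaction("zeroth", 1.0, (), (1,), noise_channel=0)])
    counts = []
    for s in range(800):
        tr = ssan_run(
            net, [0], [NoiseChannel("sine_wiener", amplitude=0.9, tau=5.0)],
            SimulationConfig(T=50.0, rng_seed=s, record_grid=np.array([50.0])),
        )
        counts.append(tr.n_events)
    counts = np.asarray(counts)
    se = counts.std(ddof=1) / math.sqrt(counts.size)
    assert abs(counts.mean() - 50.0) < 4 * se
    assert counts.var(ddof=1) > counts.mean()


def test_determinism_identical_seeds_identical_trajectories():
    net = ReactionNetwork(["X"], [Reaction("zeroth", 2.0, (), (1,), noise_channel=0),
                                  Reaction("first", 0.5, (0,), (-1,))])
    ch = [NoiseChannel("sine_wiener", amplitude=0.5, tau=2.0)]
    cfg = SimulationConfig(T=20.0, rng_seed=123, record_grid=np.linspace(0, 20, 41))
    t1 = ssan_run(net, [0], ch, cfg)
    t2 = ssan_run(net, [0], ch, cfg)
    assert np.array_equal(t1.counts, t2.counts)
    assert np.array_equal(t1.noise, t2.noise)


def test_max_events_cap_raises():
    net = ReactionNetwork(["X"], [Reaction("zeroth", 1000.0, (), (1,))])
    with pytest.raises(RunawaySimulationError):
        ssa_run(net, [0], SimulationConfig(T=100.0, max_events=50))
    with pytest.raises(RunawaySimulationError):
        ssan_run(net, [0], [], SimulationConfig(T=100.0, max_events=50))
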