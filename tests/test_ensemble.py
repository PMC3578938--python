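"""Ensembles, empirical densities, mode counting, periodicity detection."""

import math

import numpy as np
import pytest
from scipy import stats

from ssan.engine import SimulationConfig, ssan_run
from ssan.ensemble import (
    EmpiricalDensity,
    column_periodicity,
    count_modes,
    density_vs_time,
    empirical_density,
    first_peak_mass,
    mean_std,
    run_ensemble,
)
from ssan.network import Reaction, ReactionNetwork
from ssan.noise import NoiseChannel


def birth_death(kb=10.0, kd=1.0):
    return ReactionNetwork(
        ["X"],
        [Reaction("zeroth", kb, (), (1,)), Reaction("first", kd, (0,), (-1,))],
    )


@pytest.fixture(scope="module")
def bd_ensemble():
    net = birth_death()
    cfg = SimulationConfig(T=15.0, record_grid=np.linspace(0, 15, 16))
    return run_ensemble(net, [0], [], cfg, 3000, base_seed=5)


def test_single_run_matches_direct_call():
    net = birth_death()
    cfg = SimulationConfig(T=5.0, rng_seed=99, record_grid=np.linspace(0, 5, 6))
    ens = run_ensemble(net, [0], [], cfg, 1, base_seed=99)
    tr = ssan_run(net, [0], [], cfg)
    assert np.array_equal(ens.counts[0], tr.counts)


def test_ensemble_reproducible_and_runs_distinct(bd_ensemble):
    net = birth_death()
    cfg = SimulationConfig(T=5.0, record_grid=np.linspace(0, 5, 6))
    e1 = run_ensemble(net, [0], [], cfg, 20, base_seed=3)
    e2 = run_ensemble(net, [0], [], cfg, 20, base_seed=3)
    assert np.array_equal(e1.counts, e2.counts)
    hashes = {h.tobytes() for h in e1.counts}
    assert len(hashes) > 15  # distinct seeds -> (almost surely) distinct paths


def test_mean_std_poisson_stationarity(bd_ensemble):
    mu, sd = mean_std(bd_ensemble, "X")
    assert sd[0] == 0.0  # all runs start at 0
    # at stationarity mean ~ variance ~ 10
    assert mu[-1] == pytest.approx(10.0, abs=0.3)
    assert sd[-1] ** 2 == pytest.approx(10.0, rel=0.15)


def test_empirical_density_properties(bd_ensemble):
    d = empirical_density(bd_ensemble, "X", 15.0)
    assert d.probabilities.sum() == pytest.approx(1.0)
    # total-variation distance to Poisson(10) below 0.05
    pois = stats.poisson.pmf(d.support, 10.0)
    tv = 0.5 * np.abs(d.probabilities - pois).sum() + 0.5 * stats.poisson.sf(
        d.support[-1], 10.0
    )
    assert tv < 0.05


def test_density_point_mass():
    d = EmpiricalDensity("X", 0.0, np.arange(6), np.eye(6)[3])
    assert count_modes(d, n_samples=100) == 1
    assert first_peak_mass(d, n_samples=100) == 1.0


def test_density_vs_time_columns_normalized(bd_ensemble):
    support, times, mat = density_vs_time(bd_ensemble, "X")
    assert np.allclose(mat.sum(axis=0), 1.0)
    assert support[0] == 0 and times[0] == 0.0
    # the t=0 column is a point mass at the initial count
    assert mat[0, 0] == 1.0


@pytest.mark.parametrize(
    "mix,expected",
    [
        ([(10.0, 1.0)], 1),
        ([(5.0, 0.5), (60.0, 0.5)], 2),
        ([(3.0, 0.4), (25.0, 0.3), (70.0, 0.3)], 3),
    ],
)
def test_count_modes_on_poisson_mixtures(mix, expected, rng):
    n = 5000
    parts = []
    for mu, w in mix:
        parts.append(rng.poisson(mu, size=int(w * n)))
    x = np.concatenate(parts)
    support = np.arange(x.max() + 1)
    probs = np.bincount(x) / x.size
    d = EmpiricalDensity("X", 0.0, support, probs)
    assert count_modes(d, n_samples=n) == expected


def test_count_modes_two_point_masses():
    support = np.arange(101)
    probs = np.zeros(101)
    probs[0] = probs[100] = 0.5
    d = EmpiricalDensity("X", 0.0, support, probs)
    assert count_modes(d, n_samples=1000) == 2
    assert first_peak_mass(d, n_samples=1000) == pytest.approx(0.5)


def test_count_modes_bandwidth_stability(rng):
    """The mode count is invariant to +-25% bandwidth changes on the
    reference mixtures."""
    x = np.concatenate([rng.poisson(5.0, 2500), rng.poisson(60.0, 2500)])
    probs = np.bincount(x) / x.size
    d = EmpiricalDensity("X", 0.0, np.arange(probs.size), probs)
    from ssan.ensemble import _rule_of_thumb_bandwidth

    bw = _rule_of_thumb_bandwidth(d, 5000)
    for f in (0.75, 1.0, 1.25):
        assert count_modes(d, smoothing_bandwidth=f * bw, n_samples=5000) == 2


def test_column_periodicity_recovers_known_period():
    # synthetic density matrix oscillating with period 12 on a dt=1 grid
    times = np.arange(0.0, 120.0)
    support = np.arange(30)
    mat = np.empty((support.size, times.size))
    for k, t in enumerate(times):
        center = 15 + 8 * math.sin(2 * math.pi * t / 12.0)
        col = np.exp(-0.5 * ((support - center) / 2.5) ** 2)
        mat[:, k] = col / col.sum()
    per = column_periodicity(times, mat, (5.0, 30.0))
    assert per == pytest.approx(12.0, rel=0.05)


def test_empty_probability_vector_error():
    d = EmpiricalDensity.__new__(EmpiricalDensity)
    d.species, d.time = "X", 0.0
    d.support, d.probabilities = np.arange(0), np.zeros(0)
    with pytest.raises(ValueError):
        count_modes(d)
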