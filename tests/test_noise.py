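"""Laws and mechanics of the bounded-noise channels.

The Sine-Wiener checks compare Monte-Carlo statistics of the gridded driver
against the closed-form moments of B*sin(sqrt(2/tau)*W_t): mean 0, variance
(B^2/2)(1-exp(-4t/tau)), and the arcsine stationary law.
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ssan.noise import (
    NoiseChannel,
    NoiseConfigError,
    NoiseRealization,
    interpolate,
    sine_wiener_ensemble,
    sine_wiener_value,
    sine_wiener_variance,
    stationary_cdf,
    stationary_density,
)

TAU, B = 2.0, 0.8


def test_wiener_driver_starts_at_zero_with_h_variance_increments():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU, granularity=0.01)
    r = NoiseRealization(ch, seed=3)
    r.ensure(1000.0)
    W = r._W[: r._n]
    assert W[0] == 0.0
    incs = np.diff(W)
    # Var(dW) = h, checked at 4 standard errors of the sampling variance
    n = incs.size
    se = 0.01 * math.sqrt(2.0 / (n - 1))
    assert abs(incs.var() - 0.01) < 4 * se


def test_distinct_seeds_give_uncorrelated_increments():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU, granularity=0.01)
    r1, r2 = NoiseRealization(ch, seed=1), NoiseRealization(ch, seed=2)
    r1.ensure(200.0)
    r2.ensure(200.0)
    a = np.diff(r1._W[: r1._n])
    b = np.diff(r2._W[: r2._n])
    r = np.corrcoef(a, b)[0, 1]
    assert abs(r) < 4.0 / math.sqrt(a.size)


def test_sine_transform_bounds_and_zero():
    assert sine_wiener_value(B, TAU, 0.0) == 0.0
    ws = np.linspace(-50, 50, 10001)
    vals = np.array([sine_wiener_value(B, TAU, w) for w in ws])
    assert np.all(np.abs(vals) <= B + 1e-15)


def test_variance_growth_law():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU)
    times = np.array([TAU / 4, TAU, 4 * TAU])
    vals = sine_wiener_ensemble(ch, times, n_paths=4000, seed=9)
    assert np.all(np.abs(vals) <= B + 1e-12)
    for j, t in enumerate(times):
        v = sine_wiener_variance(B, TAU, t)
        sample = vals[:, j]
        assert abs(sample.mean()) < 4 * sample.std() / math.sqrt(sample.size)
        se = sample.var(ddof=1) * math.sqrt(2.0 / (sample.size - 1))
        assert abs(sample.var(ddof=1) - v) < 4 * se


def test_stationary_density_arcsine():
    assert stationary_density(1.0, 0.0) == pytest.approx(1 / math.pi)
    total, _ = integrate.quad(lambda x: stationary_density(B, x), -B, B)
    assert total == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        stationary_density(B, B)
    # long-run samples follow the arcsine law (KS at 1%)
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU)
    vals = sine_wiener_ensemble(ch, np.array([50 * TAU]), n_paths=4000, seed=5)[:, 0]
    d = stats.kstest(vals, lambda x: stationary_cdf(B, x))
    assert d.pvalue > 0.01


def test_langevin_ou_stationary_variance():
    """Euler-Maruyama OU channel reaches variance sigma^2 * tau / 2."""
    tau, sig = 1.0, 0.7
    ch = NoiseChannel(
        "langevin_generic", tau=tau, granularity=0.005,
        drift=lambda xi, x: -xi / tau, diffusion=lambda xi, x: sig,
    )
    r = NoiseRealization(ch, seed=8)
    r.ensure(400.0)
    xs = r._zeta[2000 : r._n]  # discard transient
    target = sig * sig * tau / 2.0
    # autocorrelated samples: effective n ~ n * h / (2 tau)
    n_eff = xs.size * 0.005 / (2 * tau)
    se = target * math.sqrt(2.0 / n_eff)
    assert abs(xs.var() - target) < 4 * se


def test_langevin_zero_drift_diffusion_is_frozen():
    ch = NoiseChannel(
        "langevin_generic", tau=1.0, granularity=0.01,
        drift=lambda xi, x: 0.0, diffusion=lambda xi, x: 0.0,
    )
    r = NoiseRealization(ch, seed=1, xi0=0.3)
    r.ensure(5.0)
    assert np.allclose(r._zeta[: r._n], 0.3)


def test_interpolation_exact_at_nodes_and_linear_between():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU, granularity=0.02)
    r = NoiseRealization(ch, seed=4)
    r.ensure(1.0)
    k = 10
    t_node = k * 0.02
    assert r.value(t_node) == pytest.approx(r.grid_value(k), abs=1e-12)
    mid = (r.grid_value(k) + r.grid_value(k + 1)) / 2
    assert r.value(t_node + 0.01) == pytest.approx(mid, abs=1e-12)
    assert interpolate(r, t_node) == pytest.approx(r.grid_value(k))


def test_reproducibility_bitwise_and_query_pattern_independence():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU, granularity=0.01)
    a = NoiseRealization(ch, seed=42)
    b = NoiseRealization(ch, seed=42)
    a.ensure(50.0)  # one big request
    for t in np.linspace(0, 50, 23):  # many small requests
        b.ensure(t)
    b.ensure(50.0)
    n = min(a._n, b._n)
    assert np.array_equal(a._zeta[:n], b._zeta[:n])


def test_autocorrelation_decays_on_tau_scale():
    ch = NoiseChannel("sine_wiener", amplitude=B, tau=TAU, granularity=TAU / 100)
    r = NoiseRealization(ch, seed=13)
    r.ensure(3000 * TAU)
    z = r.values
    z = z - z.mean()
    lags = [0, 50, 100, 200, 300]  # 0, tau/2, tau, 2tau, 3tau in grid units
    acf = [float(np.dot(z[: z.size - l], z[l:]) / (z.size - l)) for l in lags]
    assert all(acf[i] > acf[i + 1] for i in range(len(acf) - 1))
    assert acf[0] > 0


def test_granularity_validation():
    with pytest.raises(NoiseConfigError):
        NoiseChannel("sine_wiener", amplitude=0.5, tau=1.0, granularity=0.5)
    with pytest.raises(NoiseConfigError):
        NoiseChannel("sine_wiener", amplitude=0.5, tau=1.0, granularity=-0.01)
    with pytest.raises(NoiseConfigError):
        NoiseChannel("sine_wiener", amplitude=1.5, tau=1.0)
    ch = NoiseChannel("sine_wiener", amplitude=0.5, tau=1.0)
    assert ch.granularity == pytest.approx(0.01)  # default tau/100


def test_deterministic_periodic_channel_is_analytic():
    ch = NoiseChannel("deterministic_periodic", amplitude=0.3, tau=10.0)
    r = NoiseRealization(ch, seed=0)
    for t in (0.0, 2.5, 5.0, 7.5):
        assert r.value(t) == pytest.approx(0.3 * math.sin(2 * math.pi * t / 10.0))
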