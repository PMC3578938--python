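"""Michaelis-Menten constant, reduced propensity and validity conditions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssan.case_studies import esp_condition_a, esp_condition_b
from ssan.noise import NoiseChannel
from ssan.qssa import (
    MMParameters,
    michaelis_constant,
    mm_propensity,
    noisy_michaelis_constant,
    validity_check,
    validity_ratio,
    validity_timedep,
)


def P(k1=1.0, km1=1.0, k2=1.0, E=10, S0=100):
    return MMParameters(k1, km1, k2, E, S0)


def test_michaelis_constant_arithmetic():
    assert michaelis_constant(P(1, 1, 1)) == 2.0
    assert michaelis_constant(P(2, 0, 0)) == 0.0
    c = 7.3
    assert michaelis_constant(P(c * 1, c * 1, c * 1)) == michaelis_constant(P(1, 1, 1))
    with pytest.raises(ZeroDivisionError):
        michaelis_constant(P(k1=0.0))


def test_mm_propensity_shape():
    p = P(1, 1, 1, E=10)
    km = michaelis_constant(p)
    assert mm_propensity(0, p, km) == 0.0
    assert mm_propensity(km, p, km) == pytest.approx(p.k2 * p.E_total / 2)
    assert mm_propensity(10**9, p, km) == pytest.approx(p.k2 * p.E_total, rel=1e-3)
    assert mm_propensity(5, p, math.inf) == 0.0


def test_noisy_km_degenerations_and_arithmetic():
    p = P(1, 1, 1)
    b = {"k1": 0, "k_minus1": 1, "k2": 2}
    assert noisy_michaelis_constant(p, [0.0, 0.0, 0.0], b) == michaelis_constant(p)
    # g1 = 2, g-1 = g2 = 1 -> K_M = 2/2 = 1
    assert noisy_michaelis_constant(p, [1.0, 0.0, 0.0], b) == pytest.approx(1.0)
    # binding factor hitting zero -> +inf sentinel
    assert noisy_michaelis_constant(p, [-1.0, 0.0, 0.0], b) == math.inf


@given(
    st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)
)
@settings(max_examples=80, deadline=None)
def test_noisy_km_stays_in_interval_bound(z1, zm1, z2):
    """For |zeta| <= B < 1, K_M(t) lies in [K*(1-B)/(1+B), K*(1+B)/(1-B)]."""
    p = P(0.7, 2.0, 1.0)
    B = 0.5
    km0 = michaelis_constant(p)
    km = noisy_michaelis_constant(p, [z1, zm1, z2], {"k1": 0, "k_minus1": 1, "k2": 2})
    assert km0 * (1 - B) / (1 + B) - 1e-12 <= km <= km0 * (1 + B) / (1 - B) + 1e-12


def test_validity_ratio_regimes():
    deep = MMParameters(1, 1, 1, E_total=1, S0=10**6)
    assert validity_ratio(deep) < 1e-5
    assert validity_check(validity_ratio(deep))
    border = MMParameters(1, 0, 0, E_total=100, S0=100)
    assert validity_ratio(border, K_M=0.0) == 1.0
    assert not validity_check(1.0)


def test_fixture_conditions_straddle_the_validity_criterion():
    ra = validity_ratio(esp_condition_a())
    rb = validity_ratio(esp_condition_b())
    assert validity_check(ra, 0.05)
    assert not validity_check(rb, 0.05)
    assert ra <= 0.01  # condition A is deeply valid
    assert rb > 0.5


def test_validity_timedep_interval_bound():
    p = esp_condition_a()
    chans = [NoiseChannel("sine_wiener", amplitude=0.5, tau=1.0) for _ in range(3)]
    b = {"k1": 0, "k_minus1": 1, "k2": 2}
    # B = 0 degenerates to the static check
    chans0 = [NoiseChannel("sine_wiener", amplitude=0.0, tau=1.0) for _ in range(3)]
    assert validity_timedep(p, chans0, b) == validity_check(validity_ratio(p))
    # B = 0.5 on all three rates keeps condition A valid; grid-search oracle
    assert validity_timedep(p, chans, b)
    worst = 0.0
    km0 = michaelis_constant(p)
    for z1 in np.linspace(-0.5, 0.5, 11):
        for zm1 in np.linspace(-0.5, 0.5, 11):
            for z2 in np.linspace(-0.5, 0.5, 11):
                km = noisy_michaelis_constant(p, [z1, zm1, z2], b)
                worst = max(worst, validity_ratio(p, km))
    assert worst <= 0.05  # agrees with the interval bound's verdict
    # maximum intensity on the binding rate -> conservative failure
    chans_b1 = [NoiseChannel("sine_wiener", amplitude=1.0, tau=1.0)] + chans[1:]
    assert not validity_timedep(p, chans_b1, b)
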