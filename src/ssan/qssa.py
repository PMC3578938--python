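"""Michaelis-Menten quasi-steady-state reduction, with and without noise.

The exact enzyme-substrate-product network

    E + S -> C   (k1),    C -> E + S   (k_minus1),    C -> E + P   (k2)

reduces, when the complex is in quasi-steady state, to the single reaction
``S -> P`` with the nonlinear rate ``k2 * E_total * S / (K_M + S)`` and
``K_M = (k_minus1 + k2) / k1``.  The reduction is legitimate when a timescale
separation holds; we use the Segel-Slemrod ratio

    E_total / (S0 + K_M)  <<  1

as the validity criterion (configurable threshold, default 0.05).  With
unitary-mean bounded noises ``g = 1 + zeta`` on any of the three rate
constants the Michaelis constant becomes the time-dependent, nonlinear
function of the noises

    K_M(t) = (k_minus1 * g_-1(t) + k2 * g_2(t)) / (k1 * g_1(t)),

and the validity condition is checked conservatively over the whole noise box
``|zeta_j| <= B_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .noise import NoiseChannel

__all__ = [
    "MMParameters",
    "michaelis_constant",
    "mm_propensity",
    "noisy_michaelis_constant",
    "validity_ratio",
    "validity_check",
    "validity_timedep",
    "DEFAULT_VALIDITY_THRESHOLD",
]

DEFAULT_VALIDITY_THRESHOLD = 0.05


@dataclass
class MMParameters:
    """Rate constants and copy numbers of the enzyme-substrate-product motif."""

    k1: float
    k_minus1: float
    k2: float
    E_total: int
    S0: int

    def __post_init__(self) -> None:
        if min(self.k1, self.k_minus1, self.k2) < 0:
            raise ValueError("rate constants must be nonnegative")
        if self.E_total < 0 or self.S0 < 0:
            raise ValueError("copy numbers must be nonnegative")


def michaelis_constant(p: MMParameters) -> float:
    """``K_M = (k_minus1 + k2) / k1``."""
    if p.k1 == 0:
        raise ZeroDivisionError("K_M undefined for k1 = 0")
    return (p.k_minus1 + p.k2) / p.k1


def mm_propensity(S: float, p: MMParameters, K_M: Optional[float] = None) -> float:
    """Michaelis-Menten rate ``k2 * E_total * S / (K_M + S)``.

    Zero at ``S = 0``; half-maximal at ``S = K_M``; saturates at
    ``k2 * E_total``.  ``K_M = +inf`` (noisy zero-crossing of the binding
    rate) yields 0.
    """
    if S < 0:
        raise ValueError("substrate count must be nonnegative")
    if K_M is None:
        K_M = michaelis_constant(p)
    if S == 0:
        return 0.0
    if math.isinf(K_M):
        return 0.0
    return p.k2 * p.E_total * S / (K_M + S)


def noisy_michaelis_constant(
    p: MMParameters,
    zeta: Sequence[float],
    bindings: dict[str, int],
) -> float:
    """Time-dependent Michaelis constant under channel values ``zeta``.

    ``bindings`` maps rate names (``"k1"``, ``"k_minus1"``, ``"k2"``) to
    channel indices; unbound rates use ``g = 1``.  A zero crossing of the
    binding-rate factor (possible only at maximum intensity ``B = 1``)
    returns ``+inf``, which drives :func:`mm_propensity` to zero.
    """
    z = np.asarray(zeta, dtype=float)

    def g(rate: str) -> float:
        c = bindings.get(rate)
        if c is None:
            return 1.0
        gv = 1.0 + z[c]
        if gv < 0.0:
            raise ValueError(f"perturbation factor for {rate} below zero")
        return gv

    num = p.k_minus1 * g("k_minus1") + p.k2 * g("k2")
    den = p.k1 * g("k1")
    if den == 0.0:
        return math.inf
    return num / den


def validity_ratio(p: MMParameters, K_M: Optional[float] = None) -> float:
    """Segel-Slemrod separation ratio ``E_total / (S0 + K_M)``."""
    if K_M is None:
        K_M = michaelis_constant(p)
    den = p.S0 + K_M
    if den <= 0:
        raise ValueError("S0 + K_M must be positive")
    return p.E_total / den


def validity_check(
    ratio: float, threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> bool:
    """True when the reduction is legitimate, i.e. ``ratio <= threshold``."""
    return ratio <= threshold


def validity_timedep(
    p: MMParameters,
    channels: Sequence[NoiseChannel],
    bindings: dict[str, int],
    threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> bool:
    """Worst-case validity over the noise box ``|zeta_j| <= B_j``.

    The supremum of the separation ratio is attained at the infimum of
    ``K_M(t)``, bounded by interval arithmetic: numerator rates at
    ``1 - B``, binding rate at ``1 + B``.  Realization-independent and
    conservative.  ``B = 1`` on the binding-rate channel makes ``K_M``
    unbounded above but the governing lower end is still finite; however a
    fully vanishing numerator (both ``k_minus1`` and ``k2`` bound at
    ``B = 1``) drives the infimum of ``K_M`` to 0 and the check simply
    evaluates the resulting ratio.
    """

    def B(rate: str) -> float:
        c = bindings.get(rate)
        if c is None:
            return 0.0
        ch = channels[c]
        if ch.kind == "none":
            return 0.0
        if not ch.bounded:
            raise ValueError("worst-case validity requires bounded channels")
        return ch.amplitude

    b1 = B("k1")
    if b1 >= 1.0:
        # binding factor can reach 0: K_M(t) is unbounded above and the
        # a-priori interval bound is uninformative; flag invalid conservatively
        return False
    km_min = (p.k_minus1 * (1.0 - B("k_minus1")) + p.k2 * (1.0 - B("k2"))) / (
        p.k1 * (1.0 + b1)
    )
    sup_ratio = p.E_total / (p.S0 + km_min)
    return sup_ratio <= threshold
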