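"""Bounded colored noise channels and their discrete-grid realizations.

The workhorse is the Sine-Wiener noise

    zeta(t) = B * sin( sqrt(2/tau) * W(t) ),      W a standard Wiener process,

a bounded (|zeta| <= B), zero-mean, colored process with autocorrelation time
``tau``.  Its variance grows as ``(B^2/2) * (1 - exp(-4 t / tau))`` and its
stationary marginal follows the arcsine law on (-B, B).  It is realized
*exactly* here: the Wiener driver is sampled on a grid of spacing ``h`` (the
noise granularity, required to be much smaller than ``tau``) and the bounded
sine transform is applied pointwise, so the marginal law carries no
discretization bias.  Between grid points values are interpolated linearly.

Also provided: a generic Langevin channel (Euler-Maruyama with user drift and
diffusion, optionally dependent on the current molecule counts), and a
deterministic sinusoidal "channel" used to express periodically perturbed
rates through the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "NoiseChannel",
    "NoiseRealization",
    "NoiseConfigError",
    "sine_wiener_value",
    "sine_wiener_variance",
    "stationary_density",
    "stationary_cdf",
    "interpolate",
]

KINDS = ("sine_wiener", "langevin_generic", "deterministic_periodic", "none")

#: Wiener/Langevin increments are drawn in fixed-size blocks so that the
#: random stream consumed by a channel depends only on (seed, h), never on
#: the pattern of lazy-extension requests.
_BLOCK = 2048


class NoiseConfigError(ValueError):
    """Invalid noise-channel configuration."""


def sine_wiener_value(B: float, tau: float, W: float) -> float:
    """Bounded sine transform of a Wiener value: ``B * sin(sqrt(2/tau) * W)``."""
    return B * math.sin(math.sqrt(2.0 / tau) * W)


def sine_wiener_variance(B: float, tau: float, t: float) -> float:
    """Exact variance of the Sine-Wiener noise started at zero:
    ``(B^2 / 2) * (1 - exp(-4 t / tau))``."""
    return 0.5 * B * B * (1.0 - math.exp(-4.0 * t / tau))


def stationary_density(B: float, x: float) -> float:
    """Stationary (t >> tau) marginal density: arcsine law ``1/(pi*sqrt(B^2-x^2))``.

    Raises a domain error for ``|x| >= B``.
    """
    if abs(x) >= B:
        raise ValueError(f"|x| = {abs(x)} outside the open support (-{B}, {B})")
    return 1.0 / (math.pi * math.sqrt(B * B - x * x))


def stationary_cdf(B: float, x) -> np.ndarray:
    """CDF of the arcsine law on (-B, B): ``1/2 + arcsin(x/B)/pi``."""
    x = np.clip(np.asarray(x, dtype=np.float64), -B, B)
    return 0.5 + np.arcsin(x / B) / np.pi


@dataclass
class NoiseChannel:
    """Specification of one extrinsic-noise channel.

    Parameters
    ----------
    kind:
        ``"sine_wiener"``, ``"langevin_generic"``, ``"deterministic_periodic"``
        or ``"none"``.
    amplitude:
        Noise intensity ``B`` in [0, 1] for bounded kinds (``B = 1`` is the
        maximum admissible intensity for unitary-mean perturbations); the
        intensity ``epsilon`` for the deterministic sinusoid.
    tau:
        Autocorrelation time (for ``deterministic_periodic`` the period of
        the sinusoid).
    granularity:
        Grid spacing ``h`` of the discretized realization.  Must satisfy
        ``h <= tau/10``; defaults to ``tau/100``.
    drift, diffusion:
        For ``langevin_generic``: callables ``mu(xi, x_counts)`` and
        ``sigma(xi, x_counts)`` of the current noise value and the (frozen)
        molecule-count vector.
    name:
        Optional label.
    """

    kind: str = "sine_wiener"
    amplitude: float = 0.5
    tau: float = 1.0
    granularity: Optional[float] = None
    drift: Optional[Callable[[float, np.ndarray], float]] = None
    diffusion: Optional[Callable[[float, np.ndarray], float]] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise NoiseConfigError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none":
            if self.tau <= 0:
                raise NoiseConfigError("autocorrelation time tau must be positive")
            if self.granularity is None:
                self.granularity = self.tau / 100.0
            if self.granularity <= 0:
                raise NoiseConfigError("noise granularity h must be positive")
            if self.granularity > self.tau / 10.0 + 1e-12 * self.tau:
                raise NoiseConfigError(
                    f"granularity h = {self.granularity} too coarse: must be "
                    f"<= tau/10 = {self.tau / 10.0} (default tau/100)"
                )
        if self.kind in ("sine_wiener",) and not 0.0 <= self.amplitude <= 1.0:
            raise NoiseConfigError(
                "sine_wiener amplitude B must lie in [0, 1] for unitary-mean "
                "perturbations"
            )
        if self.kind == "langevin_generic" and (
            self.drift is None or self.diffusion is None
        ):
            raise NoiseConfigError("langevin_generic requires drift and diffusion")

    @property
    def bounded(self) -> bool:
        return self.kind in ("sine_wiener", "deterministic_periodic")


class NoiseRealization:
    """One lazily-extended trajectory of a channel on the grid t0 + k*h.

    The realization is reproducible from ``(channel, seed, t0)``: driver
    increments are consumed in fixed-size blocks, so two realizations with the
    same seed produce bitwise-identical grids no matter how they are queried.
    """

    def __init__(
        self,
        channel: NoiseChannel,
        t0: float = 0.0,
        seed: int | np.random.SeedSequence | np.random.Generator = 0,
        xi0: float = 0.0,
    ) -> None:
        self.channel = channel
        self.t0 = float(t0)
        if isinstance(seed, np.random.Generator):
            self._rng = seed
        else:
            self._rng = np.random.default_rng(seed)
        self.h = channel.granularity if channel.kind != "none" else math.inf
        k = channel.kind
        if k == "none":
            self._zeta = np.zeros(1)
            return
        self._sqrt_h = math.sqrt(self.h)
        self._n = 1  # number of valid grid points
        if k == "sine_wiener":
            self._a = math.sqrt(2.0 / channel.tau)
            self._W = np.zeros(_BLOCK + 1)
            self._zeta = np.zeros(_BLOCK + 1)
        elif k == "langevin_generic":
            self._xi = np.full(_BLOCK + 1, float(xi0))
            self._zeta = self._xi
            self._pending = np.empty(0)  # pre-drawn normals not yet consumed
        elif k == "deterministic_periodic":
            self._omega = 2.0 * math.pi / channel.tau
            # no stored grid needed; values are analytic

    # ----- grid bookkeeping -------------------------------------------------

    @property
    def grid_times(self) -> np.ndarray:
        if self.channel.kind in ("none", "deterministic_periodic"):
            return np.array([self.t0])
        return self.t0 + self.h * np.arange(self._n)

    @property
    def values(self) -> np.ndarray:
        """Channel values zeta at the grid points generated so far."""
        if self.channel.kind in ("none", "deterministic_periodic"):
            return np.array([self.value(self.t0)])
        return self._zeta[: self._n].copy()

    @property
    def last_time(self) -> float:
        if self.channel.kind in ("none", "deterministic_periodic"):
            return math.inf
        return self.t0 + (self._n - 1) * self.h

    def _grow(self, arr: np.ndarray, need: int) -> np.ndarray:
        if need <= arr.size:
            return arr
        out = np.zeros(max(need, 2 * arr.size))
        out[: arr.size] = arr
        return out

    def ensure(self, t: float, counts: Optional[np.ndarray] = None) -> None:
        """Extend the realization to cover time ``t`` (lazy, block-wise).

        ``counts`` is the frozen molecule-count vector used by state-dependent
        Langevin drift/diffusion; ignored by other kinds.
        """
        k = self.channel.kind
        if k in ("none", "deterministic_periodic"):
            return
        need = int(math.ceil((t - self.t0) / self.h - 1e-9)) + 1
        if need <= self._n:
            return
        # extend in whole fixed-size blocks, one block at a time, so both the
        # consumed random stream and the floating-point accumulation order
        # are independent of the request pattern
        n_blocks = (need - self._n + _BLOCK - 1) // _BLOCK
        if k == "sine_wiener":
            self._W = self._grow(self._W, self._n + n_blocks * _BLOCK)
            self._zeta = self._grow(self._zeta, self._n + n_blocks * _BLOCK)
            for _ in range(n_blocks):
                incs = self._rng.standard_normal(_BLOCK) * self._sqrt_h
                w = self._W[self._n - 1] + np.cumsum(incs)
                self._W[self._n : self._n + _BLOCK] = w
                self._zeta[self._n : self._n + _BLOCK] = (
                    self.channel.amplitude * np.sin(self._a * w)
                )
                self._n += _BLOCK
        else:  # langevin_generic: sequential Euler-Maruyama
            x = counts if counts is not None else np.zeros(0)
            self._xi = self._grow(self._xi, self._n + n_blocks * _BLOCK)
            mu, sig = self.channel.drift, self.channel.diffusion
            xi = float(self._xi[self._n - 1])
            h, sh = self.h, self._sqrt_h
            for _ in range(n_blocks):
                eta = self._rng.standard_normal(_BLOCK)
                for i in range(_BLOCK):
                    xi = xi + mu(xi, x) * h + sig(xi, x) * sh * eta[i]
                    self._xi[self._n + i] = xi
                self._n += _BLOCK
            self._zeta = self._xi

    # ----- evaluation -------------------------------------------------------

    def grid_value(self, k: int) -> float:
        """Value at grid point ``t0 + k*h`` (must already be generated)."""
        if self.channel.kind == "none":
            return 0.0
        if self.channel.kind == "deterministic_periodic":
            return self.channel.amplitude * math.sin(
                self._omega * (self.t0 + k * self.h - self.t0)
            )
        return float(self._zeta[k])

    def value(self, t: float, counts: Optional[np.ndarray] = None) -> float:
        """Piecewise-linear interpolation of zeta at time ``t`` (exact at nodes)."""
        k = self.channel.kind
        if k == "none":
            return 0.0
        if k == "deterministic_periodic":
            return self.channel.amplitude * math.sin(self._omega * (t - self.t0))
        self.ensure(t, counts)
        u = (t - self.t0) / self.h
        i = int(u)
        if i >= self._n - 1:
            return float(self._zeta[self._n - 1])
        frac = u - i
        z0 = self._zeta[i]
        return float(z0 + frac * (self._zeta[i + 1] - z0))

    def wiener_value(self, t: float) -> float:
        """Underlying Wiener driver W(t) (sine_wiener only), linearly interpolated."""
        if self.channel.kind != "sine_wiener":
            raise NoiseConfigError("wiener_value only defined for sine_wiener channels")
        self.ensure(t)
        u = (t - self.t0) / self.h
        i = int(u)
        if i >= self._n - 1:
            return float(self._W[self._n - 1])
        frac = u - i
        return float(self._W[i] + frac * (self._W[i + 1] - self._W[i]))


def interpolate(realization: NoiseRealization, t: float) -> float:
    """Functional alias for :meth:`NoiseRealization.value`."""
    return realization.value(t)


def sine_wiener_ensemble(
    channel: NoiseChannel,
    times: np.ndarray,
    n_paths: int,
    seed: int = 0,
    chunk: int = 2000,
) -> np.ndarray:
    """Values of ``n_paths`` independent Sine-Wiener realizations at ``times``.

    Uses the same recursive Wiener scheme as :class:`NoiseRealization`
    (grid of spacing ``h``, Gaussian increments of variance ``h``, bounded
    sine transform at the requested grid points), vectorized over paths.
    Returns an array of shape ``(n_paths, len(times))``.
    """
    if channel.kind != "sine_wiener":
        raise NoiseConfigError("ensemble sampling implemented for sine_wiener")
    h = channel.granularity
    times = np.asarray(times, dtype=np.float64)
    idx = np.rint(times / h).astype(int)
    if not np.allclose(idx * h, times, rtol=0, atol=1e-9 * max(h, 1.0)):
        raise NoiseConfigError("requested times must lie on the channel grid")
    n_steps = int(idx.max())
    a = math.sqrt(2.0 / channel.tau)
    rng = np.random.default_rng(seed)
    out = np.empty((n_paths, times.size))
    for lo in range(0, n_paths, chunk):
        hi = min(lo + chunk, n_paths)
        m = hi - lo
        W = np.zeros(m)
        take = {k: j for j, k in enumerate(idx)}
        if 0 in take:
            out[lo:hi, take[0]] = 0.0
        for k in range(1, n_steps + 1):
            W += rng.standard_normal(m) * math.sqrt(h)
            if k in take:
                out[lo:hi, take[k]] = channel.amplitude * np.sin(a * W)
    return out


def sample_stationary(
    channel: NoiseChannel, n: int, seed: int = 0, t_factor: float = 50.0
) -> np.ndarray:
    """Draw ``n`` independent samples of zeta at ``t = t_factor * tau``.

    At ``t >> tau`` the Wiener phase ``sqrt(2/tau) W(t)`` is a wide Gaussian
    and the marginal is (numerically) stationary; used as the Monte-Carlo
    oracle for the arcsine stationary law.
    """
    if channel.kind != "sine_wiener":
        raise NoiseConfigError("stationary sampling implemented for sine_wiener")
    rng = np.random.default_rng(seed)
    t = t_factor * channel.tau
    w = rng.standard_normal(n) * math.sqrt(t)
    return channel.amplitude * np.sin(math.sqrt(2.0 / channel.tau) * w)
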