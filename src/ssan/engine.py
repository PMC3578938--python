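"""Exact simulation engines: classic SSA and the bounded-noise SSAn.

The classic direct method draws the waiting time from an exponential with the
total propensity ``a_0(x)`` and picks the reaction with probability
``a_j/a_0``.  When propensities are modulated in time by extrinsic noise the
firing process of each reaction becomes an inhomogeneous Poisson process
(indeed a Cox process, since the intensity is itself random), and the waiting
time must be obtained by inverting the cumulative hazard

    Lambda_total(tau) = sum_j  integral_t^{t+tau} a_j(x, zeta(t'), t') dt'
                      = ln(1/r1),        r1 ~ U(0,1),

with the molecule counts ``x`` frozen between jumps.  The integrand is known
on the noise grid (spacing ``h``, the noise granularity) and is interpolated
linearly between nodes, so each grid segment contributes a trapezoid and the
final partial segment is solved in closed form (a quadratic in the offset).
The reaction to fire is then selected with probability proportional to the
perturbed propensities evaluated at the solved firing instant.  With all
channels disabled the machinery degenerates exactly to the direct method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import (
    HybridState,
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
    mass_action_propensity,
)
from .noise import NoiseChannel, NoiseRealization

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ssa_run",
    "ssan_run",
    "cumulative_hazard",
    "solve_jump_time",
    "select_reaction",
    "RunawaySimulationError",
]

_ORDER_CODE = {"zeroth": 0, "first": 1, "dimerization": 2, "hetero": 3}
_UNIFORM_BLOCK = 4096


class RunawaySimulationError(RuntimeError):
    """The event cap was exceeded (likely an exploding network)."""


@dataclass
class SimulationConfig:
    """Horizon, output grid, seed and numerical controls for one run."""

    t0: float = 0.0
    T: float = 10.0
    record_grid: Optional[np.ndarray] = None
    rng_seed: int = 0
    root_tolerance: float = 1e-12
    max_events: int = 50_000_000
    store_events: bool = False

    def __post_init__(self) -> None:
        if not self.t0 < self.T:
            raise ValueError("need t0 < T")
        if self.record_grid is None:
            self.record_grid = np.linspace(self.t0, self.T, 101)
        self.record_grid = np.asarray(self.record_grid, dtype=np.float64)
        if self.record_grid.size and (
            self.record_grid[0] < self.t0 - 1e-12 or self.record_grid[-1] > self.T + 1e-12
        ):
            raise ValueError("record_grid must lie within [t0, T]")


@dataclass
class Trajectory:
    """States sampled on the record grid (piecewise-constant counts,
    interpolated noise), plus optional full event log."""

    record_times: np.ndarray
    counts: np.ndarray  # (n_record, n_species) int64
    noise: np.ndarray  # (n_record, n_channels)
    n_events: int
    species_names: list[str]
    event_times: Optional[np.ndarray] = None
    event_reactions: Optional[np.ndarray] = None
    final_counts: Optional[np.ndarray] = None

    def species(self, name: str) -> np.ndarray:
        """Sampled copy-number series of one species."""
        return self.counts[:, self.species_names.index(name)]


class _UniformPool:
    """Batched U(0,1) draws from one generator (cuts per-call overhead)."""

    __slots__ = ("rng", "buf", "i")

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.buf = rng.random(_UNIFORM_BLOCK)
        self.i = 0

    def next(self) -> float:
        i = self.i
        if i >= _UNIFORM_BLOCK:
            self.buf = self.rng.random(_UNIFORM_BLOCK)
            i = 0
        self.i = i + 1
        return self.buf[i]


def _jump_rng(seed: int, n_channels: int):
    """One stream for jump decisions plus one independent sub-stream per
    channel, all derived from the run seed."""
    children = np.random.SeedSequence(seed).spawn(1 + n_channels)
    return (
        np.random.default_rng(children[0]),
        [np.random.default_rng(c) for c in children[1:]],
    )


def _compile(network: ReactionNetwork):
    """Flatten reactions into plain tuples for the inner loops."""
    ma, gen = [], []
    for j, r in enumerate(network.reactions):
        deltas = [
            (i, int(d)) for i, d in enumerate(network.stoichiometry[:, j]) if d != 0
        ]
        if r.order == "generalized":
            gen.append((j, r.propensity_fn, deltas, r.time_breakpoints))
        else:
            code = _ORDER_CODE[r.order]
            i1 = r.reactants[0] if r.reactants else -1
            i2 = r.reactants[1] if len(r.reactants) > 1 else -1
            chan = -1 if r.noise_channel is None else r.noise_channel
            ma.append((j, code, r.rate_constant, i1, i2, chan, deltas))
    return ma, gen


def _ma_base(ma, x):
    """Base mass-action propensities at frozen counts (list parallel to ma)."""
    out = []
    for _, code, k, i1, i2, _, _ in ma:
        if code == 0:
            a = k
        elif code == 1:
            a = k * x[i1]
        elif code == 2:
            a = k * x[i1] * (x[i1] - 1) * 0.5
        else:
            a = k * x[i1] * x[i2]
        out.append(a if a > 0.0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# classic SSA (direct method)
# ---------------------------------------------------------------------------


def ssa_run(
    network: ReactionNetwork,
    x0: Sequence[int],
    config: SimulationConfig,
) -> Trajectory:
    """Exact direct-method realization of a noise-free network.

    Generalized propensities are evaluated with a zero noise vector and the
    current time and treated as constant between events (valid for
    time-homogeneous rate laws such as the Michaelis-Menten reduction).
    """
    rng, _ = _jump_rng(config.rng_seed, 0)
    pool = _UniformPool(rng)
    ma, gen = _compile(network)
    n_chan = max(network.noise_channel_indices(), default=-1) + 1
    zeta0 = np.zeros(n_chan)
    x = [int(v) for v in x0]
    if min(x) < 0:
        raise ValueError("negative initial counts")
    rec = config.record_grid
    n_rec = rec.size
    counts_out = np.empty((n_rec, len(x)), dtype=np.int64)
    ri = 0
    t = config.t0
    T = config.T
    ev_t = []
    n_events = 0

    while True:
        base = _ma_base(ma, x)
        props = [(ma[i][0], base[i], ma[i][6]) for i in range(len(ma))]
        for j, fn, deltas, _ in gen:
            a = fn(np.asarray(x), zeta0, t)
            props.append((j, a if a > 0.0 else 0.0, deltas))
        a0 = 0.0
        for _, a, _ in props:
            a0 += a
        if a0 <= 0.0:
            break
        r1 = pool.next()
        while r1 <= 0.0:
            r1 = pool.next()
        t_new = t + (-math.log(r1)) / a0
        if t_new > T:
            break
        while ri < n_rec and rec[ri] < t_new:
            counts_out[ri] = x
            ri += 1
        thr = pool.next() * a0
        acc = 0.0
        deltas = props[-1][2]
        for _, a, d in props:
            acc += a
            if acc >= thr:
                deltas = d
                break
        for i, dlt in deltas:
            x[i] += dlt
        t = t_new
        n_events += 1
        if config.store_events:
            ev_t.append(t)
        if n_events >= config.max_events:
            raise RunawaySimulationError(
                f"exceeded max_events = {config.max_events} at t = {t}"
            )
    while ri < n_rec:
        counts_out[ri] = x
        ri += 1
    return Trajectory(
        record_times=rec.copy(),
        counts=counts_out,
        noise=np.zeros((n_rec, n_chan)),
        n_events=n_events,
        species_names=list(network.species_names),
        event_times=np.asarray(ev_t) if config.store_events else None,
        final_counts=np.asarray(x, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# SSAn: hazard machinery
# ---------------------------------------------------------------------------

_NUDGE = 1e-12


def _intensity(ma_base, ma, gen, reals, xarr, t, t_nudged=None):
    """Total perturbed propensity at time t with frozen counts.

    ``t_nudged`` (if given) is the time used for generalized propensities,
    pushed into the open integration segment so one-sided limits of
    discontinuous rate laws are picked up correctly.
    """
    lam = 0.0
    for i in range(len(ma)):
        a = ma_base[i]
        if a == 0.0:
            continue
        c = ma[i][5]
        if c >= 0:
            g = 1.0 + reals[c].value(t)
            if g < 0.0:
                g = 0.0
            a *= g
        lam += a
    if gen:
        tg = t if t_nudged is None else t_nudged
        zeta = np.array([r.value(tg) for r in reals])
        for _, fn, _, _ in gen:
            a = fn(xarr, zeta, tg)
            if a > 0.0:
                lam += a
    return lam


def _gather_breakpoints(gen, lo, hi):
    """Sorted generalized-propensity discontinuities inside (lo, hi)."""
    pts = [b for _, _, _, brks in gen for b in brks if lo < b < hi]
    pts.sort()
    return pts


def _march_and_solve(
    ma, ma_base, gen, reals, xarr, t, target, T_stop, h_int, counts_np, grid_origin=0.0
):
    """March the noise grid from ``t`` accumulating the total hazard until it
    brackets ``target``; solve the bracketing trapezoid segment in closed
    form.  Returns the firing time, or ``None`` if the hazard does not reach
    the target by ``T_stop``."""
    eps = _NUDGE * max(1.0, abs(t))
    lam_lo = _intensity(ma_base, ma, gen, reals, xarr, t, t + eps)
    acc = 0.0
    s_lo = t
    # segment boundaries: noise-grid nodes (origin + k*h), split at
    # generalized-propensity breakpoints
    brks = _gather_breakpoints(gen, t, T_stop + 10.0 * h_int) if gen else []
    bi = 0
    k = math.floor((t - grid_origin + 1e-12) / h_int) + 1
    while True:
        s_hi = grid_origin + k * h_int
        if bi < len(brks) and brks[bi] < s_hi - 1e-15:
            s_hi = brks[bi]
            bi += 1
            split_at_break = True
        else:
            if bi < len(brks) and brks[bi] <= s_hi + 1e-15:
                bi += 1
            k += 1
            split_at_break = False
        if s_hi <= s_lo:
            continue
        for r in reals:
            r.ensure(s_hi, counts_np)
        eps = _NUDGE * max(1.0, abs(s_hi))
        lam_hi = _intensity(ma_base, ma, gen, reals, xarr, s_hi, s_hi - eps)
        if lam_lo < -1e-9 or lam_hi < -1e-9:
            raise RuntimeError("negative total intensity during hazard marching")
        dt = s_hi - s_lo
        seg = 0.5 * (lam_lo + lam_hi) * dt
        if acc + seg >= target:
            rem = target - acc
            m = (lam_hi - lam_lo) / dt
            if abs(m) * dt < 1e-14 * max(lam_lo, 1e-300):
                u = rem / lam_lo if lam_lo > 0.0 else dt
            else:
                disc = lam_lo * lam_lo + 2.0 * m * rem
                if disc < 0.0:
                    disc = 0.0
                u = (math.sqrt(disc) - lam_lo) / m if m != 0.0 else rem / lam_lo
            if u < 0.0:
                u = 0.0
            if u > dt:
                u = dt
            t_fire = s_lo + u
            return t_fire if t_fire <= T_stop else None
        acc += seg
        s_lo = s_hi
        if split_at_break:
            # re-evaluate on the right side of the discontinuity
            eps = _NUDGE * max(1.0, abs(s_lo))
            lam_lo = _intensity(ma_base, ma, gen, reals, xarr, s_lo, s_lo + eps)
        else:
            lam_lo = lam_hi
        if s_lo >= T_stop:
            return None


def cumulative_hazard(
    network: ReactionNetwork,
    state: HybridState,
    realizations: Sequence[NoiseRealization],
    t: float,
    tau_cand: float,
) -> np.ndarray:
    """Per-reaction cumulative hazards Lambda_j over [t, t + tau_cand].

    Counts are frozen at ``state.counts``; the integrand is trapezoidal on
    the noise grid with closed-form partial end segments.  Nonnegative and
    nondecreasing in ``tau_cand``.
    """
    if tau_cand < 0:
        raise ValueError("tau_cand must be nonnegative")
    xarr = np.asarray(state.counts)
    x = [int(v) for v in state.counts]
    ma, gen = _compile(network)
    base_list = _ma_base(ma, x)
    h_int = min(
        (r.h for r in realizations if math.isfinite(r.h)), default=max(tau_cand, 1e-9)
    )
    out = np.zeros(network.n_reactions)
    t_end = t + tau_cand
    if tau_cand == 0.0:
        return out

    def a_j(jidx, tt, tt_nudged):
        r = network.reactions[jidx]
        if r.order == "generalized":
            zeta = np.array([rr.value(tt_nudged) for rr in realizations])
            a = r.propensity_fn(xarr, zeta, tt_nudged)
            return a if a > 0.0 else 0.0
        # find base
        for i, entry in enumerate(ma):
            if entry[0] == jidx:
                a = base_list[i]
                c = entry[5]
                break
        if c >= 0:
            g = 1.0 + realizations[c].value(tt)
            a *= max(g, 0.0)
        return a

    # build segment boundaries across [t, t_end]
    brks = _gather_breakpoints(gen, t, t_end)
    origin = realizations[0].t0 if len(realizations) else 0.0
    nodes = [t]
    k = math.floor((t - origin + 1e-12) / h_int) + 1
    while origin + k * h_int < t_end - 1e-15:
        nodes.append(origin + k * h_int)
        k += 1
    nodes.extend(brks)
    nodes.append(t_end)
    nodes = sorted(set(nodes))
    for r in realizations:
        r.ensure(t_end, xarr)
    for j in range(network.n_reactions):
        total = 0.0
        for s0, s1 in zip(nodes[:-1], nodes[1:]):
            e0 = _NUDGE * max(1.0, abs(s0))
            e1 = _NUDGE * max(1.0, abs(s1))
            a0 = a_j(j, s0, s0 + e0)
            a1 = a_j(j, s1, s1 - e1)
            total += 0.5 * (a0 + a1) * (s1 - s0)
        out[j] = total
    return out


def solve_jump_time(
    network: ReactionNetwork,
    state: HybridState,
    realizations: Sequence[NoiseRealization],
    t: float,
    r1: float,
    T: float = math.inf,
) -> float:
    """Smallest tau with ``Lambda_total(tau) = ln(1/r1)``; ``inf`` if the
    target is not reached by ``T`` (end of horizon)."""
    if not 0.0 < r1 < 1.0:
        raise ValueError("r1 must lie in (0, 1)")
    target = -math.log(r1)
    x = [int(v) for v in state.counts]
    xarr = np.asarray(state.counts)
    ma, gen = _compile(network)
    base = _ma_base(ma, x)
    h_int = _integration_step(realizations, t, T)
    T_stop = T if math.isfinite(T) else t + 1e12
    origin = realizations[0].t0 if realizations else 0.0
    t_fire = _march_and_solve(
        ma, base, gen, realizations, xarr, t, target, T_stop, h_int, xarr, origin
    )
    return math.inf if t_fire is None else t_fire - t


def _integration_step(realizations, t0, T):
    """Hazard-integration step: the finest channel granularity, or a
    256-segment fallback when no gridded channel is active."""
    h = min((r.h for r in realizations if math.isfinite(r.h)), default=math.inf)
    if math.isfinite(h):
        return h
    span = (T - t0) if math.isfinite(T) else 1.0
    return max(span / 256.0, 1e-9)


def select_reaction(
    network: ReactionNetwork,
    state: HybridState,
    realizations: Sequence[NoiseRealization],
    t_fire: float,
    r2: float,
) -> int:
    """Reaction index drawn with probability proportional to the perturbed
    propensities evaluated at the firing instant."""
    x = [int(v) for v in state.counts]
    xarr = np.asarray(state.counts)
    ma, gen = _compile(network)
    base = _ma_base(ma, x)
    for attempt in range(2):
        tt = t_fire + attempt * 1e-9 * max(1.0, abs(t_fire))
        props = []
        for i, entry in enumerate(ma):
            a = base[i]
            c = entry[5]
            if c >= 0 and a > 0.0:
                a *= max(1.0 + realizations[c].value(tt), 0.0)
            props.append((entry[0], a))
        if gen:
            zeta = np.array([r.value(tt) for r in realizations])
            for j, fn, _, _ in gen:
                props.append((j, max(fn(xarr, zeta, tt), 0.0)))
        a_tot = sum(a for _, a in props)
        if a_tot > 0.0:
            thr = r2 * a_tot
            acc = 0.0
            for j, a in props:
                acc += a
                if acc >= thr:
                    return j
            return props[-1][0]
    raise RuntimeError("total propensity identically zero at the firing time")


# ---------------------------------------------------------------------------
# SSAn main loop
# ---------------------------------------------------------------------------


def ssan_run(
    network: ReactionNetwork,
    x0: Sequence[int],
    channels: Sequence[NoiseChannel],
    config: SimulationConfig,
) -> Trajectory:
    """Exact realization of the doubly stochastic jump process.

    Per event: draw ``r1, r2``; invert the total cumulative hazard (marching
    the noise grid, lazily extending the noise realization with the frozen
    counts); select the reaction at the firing instant; apply the
    stoichiometric change.  The noise state is never reset at jumps.  With
    all channels of kind ``"none"`` (or no channels) this reduces exactly to
    the direct method.
    """
    channels = list(channels)
    for c in network.noise_channel_indices():
        if c >= len(channels):
            raise NetworkConfigError(
                f"reaction bound to channel {c} but only {len(channels)} declared"
            )
    rng, chan_rngs = _jump_rng(config.rng_seed, len(channels))
    pool = _UniformPool(rng)
    reals = [
        NoiseRealization(ch, config.t0, chan_rngs[i]) for i, ch in enumerate(channels)
    ]
    ma, gen = _compile(network)
    active = any(ch.kind != "none" for ch in channels)
    time_dependent = active or any(brks for _, _, _, brks in gen)

    x = [int(v) for v in x0]
    if x and min(x) < 0:
        raise ValueError("negative initial counts")
    rec = config.record_grid
    n_rec = rec.size
    counts_out = np.empty((n_rec, len(x)), dtype=np.int64)
    ri = 0
    t = config.t0
    T = config.T
    h_int = _integration_step(reals, config.t0, T)
    ev_t, ev_j = [], []
    n_events = 0
    zeta0 = np.zeros(len(channels))

    while t < T:
        xarr = np.asarray(x)
        base = _ma_base(ma, x)
        r1 = pool.next()
        while r1 <= 0.0:
            r1 = pool.next()
        if not time_dependent:
            # degenerate (noise-free) case: closed-form exponential jump
            a0 = sum(base)
            if gen:
                for _, fn, _, _ in gen:
                    a0 += max(fn(xarr, zeta0, t), 0.0)
            if a0 <= 0.0:
                break
            t_fire = t + (-math.log(r1)) / a0
            if t_fire > T:
                break
        else:
            target = -math.log(r1)
            t_fire = _march_and_solve(
                ma, base, gen, reals, xarr, t, target, T, h_int, xarr, config.t0
            )
            if t_fire is None:
                break
        while ri < n_rec and rec[ri] < t_fire:
            counts_out[ri] = x
            ri += 1
        r2 = pool.next()
        # selection at the firing instant
        if not time_dependent:
            props = [(ma[i][0], base[i], ma[i][6]) for i in range(len(ma))]
            for j, fn, deltas, _ in gen:
                props.append((j, max(fn(xarr, zeta0, t), 0.0), deltas))
        else:
            props = []
            for i in range(len(ma)):
                a = base[i]
                c = ma[i][5]
                if c >= 0 and a > 0.0:
                    a *= max(1.0 + reals[c].value(t_fire), 0.0)
                props.append((ma[i][0], a, ma[i][6]))
            if gen:
                zeta = np.array([r.value(t_fire) for r in reals])
                for j, fn, deltas, _ in gen:
                    props.append((j, max(fn(xarr, zeta, t_fire), 0.0), deltas))
        a_tot = sum(a for _, a, _ in props)
        if a_tot <= 0.0:
            # can only happen at an exact zero-crossing of a maximum-intensity
            # noise; nudge forward once
            t_fire += 1e-9 * max(1.0, t_fire)
            if time_dependent:
                props = []
                for i in range(len(ma)):
                    a = base[i]
                    c = ma[i][5]
                    if c >= 0 and a > 0.0:
                        a *= max(1.0 + reals[c].value(t_fire), 0.0)
                    props.append((ma[i][0], a, ma[i][6]))
                if gen:
                    zeta = np.array([r.value(t_fire) for r in reals])
                    for j, fn, deltas, _ in gen:
                        props.append((j, max(fn(xarr, zeta, t_fire), 0.0), deltas))
                a_tot = sum(a for _, a, _ in props)
            if a_tot <= 0.0:
                raise RuntimeError("zero total propensity at the solved jump time")
        thr = r2 * a_tot
        acc = 0.0
        jsel, deltas = props[-1][0], props[-1][2]
        for j, a, d in props:
            acc += a
            if acc >= thr:
                jsel, deltas = j, d
                break
        for i, dlt in deltas:
            x[i] += dlt
            if x[i] < 0:
                raise RuntimeError(
                    f"reaction {jsel} drove species {i} negative at t = {t_fire}"
                )
        t = t_fire
        n_events += 1
        if config.store_events:
            ev_t.append(t)
            ev_j.append(jsel)
        if n_events >= config.max_events:
            raise RunawaySimulationError(
                f"exceeded max_events = {config.max_events} at t = {t} "
                f"(last reaction {jsel})"
            )
    while ri < n_rec:
        counts_out[ri] = x
        ri += 1
    # co-recorded noise values on the output grid
    noise_out = np.zeros((n_rec, len(channels)))
    for c, r in enumerate(reals):
        if channels[c].kind == "none":
            continue
        for i_, tt in enumerate(rec):
            noise_out[i_, c] = r.value(tt)
    return Trajectory(
        record_times=rec.copy(),
        counts=counts_out,
        noise=noise_out,
        n_events=n_events,
        species_names=list(network.species_names),
        event_times=np.asarray(ev_t) if config.store_events else None,
        event_reactions=np.asarray(ev_j) if config.store_events else None,
        final_counts=np.asarray(x, dtype=np.int64),
    )
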