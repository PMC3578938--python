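"""Reaction networks, hybrid states, and (perturbed) propensity evaluation.

A :class:`ReactionNetwork` holds ``N`` species and ``M`` reactions.  Each
reaction carries a stoichiometric change vector (one column of the network's
``N x M`` stoichiometry matrix) and a propensity descriptor: either one of the
standard mass-action forms (zeroth order, first order, homodimerization,
heterodimerization) or an arbitrary "generalized" nonnegative function of the
state, the noise vector and time (used by the Michaelis-Menten reduction and
the toggle-switch synthesis terms).

Extrinsic noise enters multiplicatively: a reaction bound to noise channel
``c`` has effective propensity ``a_j(x) * g_c(t)`` with ``g = 1 + zeta`` a
unitary-mean perturbation factor, ``|zeta| <= B <= 1``.  Several reactions may
share one channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "HybridState",
    "mass_action_propensity",
    "perturbed_propensity",
    "apply_stoichiometry",
    "InvalidStateError",
    "NoiseBoundViolation",
    "NetworkConfigError",
]

#: recognized mass-action orders
MASS_ACTION_ORDERS = ("zeroth", "first", "dimerization", "hetero")


class InvalidStateError(ValueError):
    """A molecule-count vector is invalid (e.g. negative counts)."""


class NoiseBoundViolation(ValueError):
    """A perturbation factor g = 1 + zeta fell below zero (misconfigured channel)."""


class NetworkConfigError(ValueError):
    """Structurally invalid network definition."""


# generalized propensity: f(counts, zeta_vector, t) -> nonnegative float
GeneralizedPropensity = Callable[[np.ndarray, np.ndarray, float], float]


@dataclass
class Reaction:
    """One reaction channel.

    Parameters
    ----------
    order:
        ``"zeroth"``, ``"first"``, ``"dimerization"`` (2 A -> ...),
        ``"hetero"`` (A + B -> ...) or ``"generalized"``.
    rate_constant:
        Nonnegative stochastic rate constant ``k`` (ignored for generalized
        reactions, whose callable owns all parameters).
    reactants:
        Indices of consumed species.  Empty for zeroth order; one index for
        first order and homodimerization; two distinct indices for ``hetero``.
    stoich:
        State-change vector ``nu_j`` (length = number of species).
    noise_channel:
        Index of the bound noise channel, or ``None`` for a noise-free
        reaction.  Mass-action reactions see only their own channel's factor;
        generalized reactions receive the full noise vector.
    propensity_fn:
        For ``order="generalized"``: callable ``f(counts, zeta, t)``.
    time_breakpoints:
        Optional sorted times at which a generalized propensity is
        discontinuous in ``t``; the simulation engine splits its hazard
        integration at these points so step-function rates integrate exactly.
    name:
        Optional label used in logs and config export.
    """

    order: str
    rate_constant: float = 0.0
    reactants: tuple[int, ...] = ()
    stoich: tuple[int, ...] = ()
    noise_channel: Optional[int] = None
    propensity_fn: Optional[GeneralizedPropensity] = None
    time_breakpoints: tuple[float, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.order not in MASS_ACTION_ORDERS + ("generalized",):
            raise NetworkConfigError(f"unknown reaction order {self.order!r}")
        if self.order != "generalized" and self.rate_constant < 0:
            raise NetworkConfigError("rate_constant must be nonnegative")
        if self.order == "zeroth" and self.reactants:
            raise NetworkConfigError("zeroth-order reaction cannot have reactants")
        if self.order == "first" and len(self.reactants) != 1:
            raise NetworkConfigError("first-order reaction needs exactly one reactant")
        if self.order == "dimerization" and len(self.reactants) != 1:
            raise NetworkConfigError("dimerization needs exactly one reactant species")
        if self.order == "hetero" and (
            len(self.reactants) != 2 or self.reactants[0] == self.reactants[1]
        ):
            raise NetworkConfigError("hetero reaction needs two distinct reactants")
        if self.order == "generalized" and self.propensity_fn is None:
            raise NetworkConfigError("generalized reaction needs a propensity_fn")


@dataclass
class ReactionNetwork:
    """Species, reactions and the stoichiometry matrix (column per reaction)."""

    species_names: list[str]
    reactions: list[Reaction]
    stoichiometry: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.species_names)
        if len(set(self.species_names)) != n:
            raise NetworkConfigError("duplicate species names")
        cols = []
        for j, rxn in enumerate(self.reactions):
            nu = np.asarray(rxn.stoich, dtype=np.int64)
            if nu.shape != (n,):
                raise NetworkConfigError(
                    f"reaction {j} ({rxn.name!r}): stoich length {nu.size} != {n} species"
                )
            for i in rxn.reactants:
                if not 0 <= i < n:
                    raise NetworkConfigError(
                        f"reaction {j} ({rxn.name!r}): reactant index {i} out of range"
                    )
            cols.append(nu)
        self.stoichiometry = (
            np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.int64)
        )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def noise_channel_indices(self) -> set[int]:
        """Channel indices referenced by any reaction."""
        return {r.noise_channel for r in self.reactions if r.noise_channel is not None}


@dataclass
class HybridState:
    """Joint state of the jump-diffusion process: counts, noise values, time."""

    counts: np.ndarray
    noise_state: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.noise_state = np.asarray(self.noise_state, dtype=np.float64)
        if np.any(self.counts < 0):
            raise InvalidStateError("negative molecule counts")


def mass_action_propensity(reaction: Reaction, counts: Sequence[int]) -> float:
    """Standard Gillespie propensity of a mass-action reaction at ``counts``.

    Forms: ``k`` (zeroth), ``k*X_i`` (first), ``k*X_i*(X_i-1)/2``
    (homodimerization), ``k*X_i*X_i'`` (heterodimerization).  Returns 0 when
    reactant copies are insufficient.
    """
    k = reaction.rate_constant
    order = reaction.order
    if order == "zeroth":
        return k
    x0 = counts[reaction.reactants[0]]
    if x0 < 0:
        raise InvalidStateError("negative molecule counts")
    if order == "first":
        return k * x0
    if order == "dimerization":
        return k * x0 * (x0 - 1) / 2.0
    if order == "hetero":
        x1 = counts[reaction.reactants[1]]
        if x1 < 0:
            raise InvalidStateError("negative molecule counts")
        return k * x0 * x1
    raise NetworkConfigError(
        "mass_action_propensity called on a generalized reaction"
    )


def perturbed_propensity(
    reaction: Reaction,
    counts: Sequence[int],
    noise_values: Sequence[float],
    t: float = 0.0,
) -> float:
    """Noise-modulated propensity ``g * a_j`` with ``g = 1 + zeta``.

    ``noise_values`` is the full channel vector ``zeta(t)``; an unbound
    mass-action reaction uses ``g = 1``.  Generalized reactions receive the
    whole vector and may depend on it nonlinearly.
    """
    if reaction.order == "generalized":
        zeta = np.asarray(noise_values, dtype=np.float64)
        a = reaction.propensity_fn(np.asarray(counts), zeta, t)
        if a < 0:
            raise NoiseBoundViolation(
                f"generalized propensity {reaction.name!r} returned {a} < 0"
            )
        return a
    base = mass_action_propensity(reaction, counts)
    c = reaction.noise_channel
    if c is None:
        return base
    g = 1.0 + noise_values[c]
    if g < 0.0:
        raise NoiseBoundViolation(
            f"perturbation factor g = {g} < 0 on channel {c} "
            "(noise exceeds the unitary-mean bound)"
        )
    return g * base


def apply_stoichiometry(state: HybridState, network: ReactionNetwork, j: int) -> HybridState:
    """Fire reaction ``j``: counts += nu_j; time and noise state unchanged."""
    nu = network.stoichiometry[:, j]
    new_counts = state.counts + nu
    if np.any(new_counts < 0):
        raise InvalidStateError(
            f"firing reaction {j} drove a count negative (internal inconsistency)"
        )
    return HybridState(new_counts, state.noise_state.copy(), state.time)
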