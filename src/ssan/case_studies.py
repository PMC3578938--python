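"""Case-study networks: enzyme kinetics, the futile cycle, the toggle switch.

Each builder returns a :class:`Fixture` bundling the reaction network, the
noise channels, the initial counts and a provenance note for every numeric
parameter.  The network *structures* follow the published models; all numeric
rate constants, copy numbers, noise intensities and autocorrelation times are
repo-chosen defaults, selected to sit clearly inside the qualitative regimes
the models are known for (valid/invalid quasi-steady state; unimodal vs.
noise-induced bimodal futile cycle; bistable toggle switch) and documented in
``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import NetworkConfigError, Reaction, ReactionNetwork
from .noise import NoiseChannel
from .qssa import MMParameters, mm_propensity, noisy_michaelis_constant

__all__ = [
    "Fixture",
    "build_esp",
    "build_futile_cycle",
    "build_toggle_switch",
    "esp_condition_a",
    "esp_condition_b",
    "list_fixtures",
    "FUTILE_DEFAULTS",
    "TOGGLE_DEFAULTS",
    "TOGGLE_TAU_SCAN",
]


@dataclass
class Fixture:
    """A ready-to-simulate model: network + channels + initial counts."""

    name: str
    variant: str
    network: ReactionNetwork
    channels: list[NoiseChannel]
    x0: np.ndarray
    parameters: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Enzyme-Substrate-Product
# ---------------------------------------------------------------------------

#: Condition A satisfies the separation criterion deeply
#: (ratio = 10 / (1000 + 200) ~ 0.0083); condition B violates it
#: (ratio = 100 / (100 + 10) ~ 0.91).  Rates are repo-chosen.
def esp_condition_a() -> MMParameters:
    return MMParameters(k1=0.01, k_minus1=1.0, k2=1.0, E_total=10, S0=1000)


def esp_condition_b() -> MMParameters:
    return MMParameters(k1=1.0, k_minus1=5.0, k2=5.0, E_total=100, S0=100)


_ESP_RATES = ("k1", "k_minus1", "k2")


def build_esp(
    variant: str,
    p: Optional[MMParameters] = None,
    bindings: Optional[dict[str, NoiseChannel]] = None,
) -> Fixture:
    """Enzyme-Substrate-Product network.

    ``variant="exact"``: three mass-action reactions over (E, S, C, P).
    ``variant="mm_reduced"``: one generalized reaction S -> P with the
    (noisy) Michaelis-Menten propensity over (S, P).

    ``bindings`` attaches independent noise channels to any subset of the
    rate names ``k1``, ``k_minus1``, ``k2``; both variants share the channel
    ordering so their noise realizations are comparable.
    """
    if p is None:
        p = esp_condition_a()
    bindings = dict(bindings or {})
    for key in bindings:
        if key not in _ESP_RATES:
            raise NetworkConfigError(f"unknown rate {key!r}; expected one of {_ESP_RATES}")
    channels = []
    chan_idx: dict[str, int] = {}
    for rate in _ESP_RATES:  # fixed order k1, k_minus1, k2
        if rate in bindings:
            chan_idx[rate] = len(channels)
            channels.append(bindings[rate])

    if variant == "exact":
        species = ["E", "S", "C", "P"]
        reactions = [
            Reaction(
                "hetero", p.k1, (0, 1), (-1, -1, +1, 0),
                noise_channel=chan_idx.get("k1"), name="binding",
            ),
            Reaction(
                "first", p.k_minus1, (2,), (+1, +1, -1, 0),
                noise_channel=chan_idx.get("k_minus1"), name="unbinding",
            ),
            Reaction(
                "first", p.k2, (2,), (+1, 0, -1, +1),
                noise_channel=chan_idx.get("k2"), name="catalysis",
            ),
        ]
        x0 = np.array([p.E_total, p.S0, 0, 0])
    elif variant == "mm_reduced":
        species = ["S", "P"]
        idx_map = dict(chan_idx)

        def mm_rate(counts, zeta, t, _p=p, _idx=idx_map):
            # both the Michaelis constant and the catalytic rate carry their
            # channel factors: v = k2 g2 E_tot S / (K_M(t) + S)
            km = noisy_michaelis_constant(_p, zeta, _idx)
            g2 = 1.0 + zeta[_idx["k2"]] if "k2" in _idx else 1.0
            return max(g2, 0.0) * mm_propensity(counts[0], _p, km)

        reactions = [
            Reaction(
                "generalized", reactants=(0,), stoich=(-1, +1),
                propensity_fn=mm_rate, name="mm_conversion",
            )
        ]
        x0 = np.array([p.S0, 0])
    else:
        raise NetworkConfigError(f"unknown ESP variant {variant!r}")
    return Fixture(
        name="esp",
        variant=variant,
        network=ReactionNetwork(species, reactions),
        channels=channels,
        x0=x0,
        parameters={
            "k1": p.k1, "k_minus1": p.k_minus1, "k2": p.k2,
            "E_total": p.E_total, "S0": p.S0,
            "bindings": dict(chan_idx),
        },
        provenance={
            "structure": "published-model",
            "rates": "repo-chosen",
            "copy_numbers": "repo-chosen",
        },
    )


# ---------------------------------------------------------------------------
# Futile cycle
# ---------------------------------------------------------------------------

#: Repo-chosen defaults.  The two interconversion arms are asymmetric: the
#: forward enzyme E1 is saturated (K_M,f = 4.5 << 100 substrate copies) and
#: runs at its maximal velocity, while the backward enzyme E2 is
#: binding-limited (K_M,b ~ 43) with twice the catalytic capacity, so the
#: backward flux is roughly linear in S* and in the E2+S* binding rate.
#: Noise-free the flux balance pins S* in a narrow unimodal band around 43.
#: A Sine-Wiener noise (B = 0.9, slow compared with the ~15-time-unit cycle
#: relaxation) on the E2 + S* binding rate moves the balance point to
#: ~ 43/g: the arcsine concentration of g = 1 + zeta near 1.9 produces a
#: sharp low mode, while g below ~0.5 cannot carry the forward flux at all
#: and the substrate pool converts almost completely, accumulating a second
#: mode at the top of the pool -- a noise-induced bimodal transition.
FUTILE_DEFAULTS = {
    "k_bind_f": 2.0,     # E1 + S association
    "k_unbind_f": 3.0,   # C1 dissociation
    "k_cat_f": 6.0,      # C1 -> E1 + S*
    "k_bind_b": 0.35,    # E2 + S* association (noise target)
    "k_unbind_b": 3.0,   # C2 dissociation
    "k_cat_b": 12.0,     # C2 -> E2 + S
    "n_substrate": 100,
    "n_enzyme": 1,       # copies of each of E1, E2
    "noise_B": 0.9,
    "noise_tau": 100.0,
    # F-subsystem (variant "with_F"): slowly fluctuating sequestration of E2
    "k_F_synth": 0.167,  # 0 -> F
    "k_F_deg": 0.0167,   # F -> 0   (mean ~10 copies, relaxation ~60 time units)
    "k_F_bind": 0.2,     # E2 + F -> E2F
    "k_F_unbind": 0.05,  # E2F -> E2 + F
}


def build_futile_cycle(
    variant: str = "noise_free",
    params: Optional[dict] = None,
) -> Fixture:
    """Enzymatic futile cycle S <-> S* driven by opposing enzymes E1, E2.

    Variants: ``"noise_free"`` (6 mass-action reactions over
    E1, S, C1, S*, E2, C2); ``"with_F"`` (adds species F, E2F and four
    mass-action reactions sequestering E2, the intrinsic route to enzyme-
    number fluctuations); ``"bounded_noise"`` (noise-free topology plus one
    Sine-Wiener channel on the E2 + S* binding reaction).
    """
    q = dict(FUTILE_DEFAULTS)
    if params:
        q.update(params)
    species = ["E1", "S", "C1", "Sstar", "E2", "C2"]
    noise_idx = 0 if variant == "bounded_noise" else None
    reactions = [
        Reaction("hetero", q["k_bind_f"], (0, 1), (-1, -1, +1, 0, 0, 0), name="bind_fwd"),
        Reaction("first", q["k_unbind_f"], (2,), (+1, +1, -1, 0, 0, 0), name="unbind_fwd"),
        Reaction("first", q["k_cat_f"], (2,), (+1, 0, -1, +1, 0, 0), name="cat_fwd"),
        Reaction(
            "hetero", q["k_bind_b"], (4, 3), (0, 0, 0, -1, -1, +1),
            noise_channel=noise_idx, name="bind_back",
        ),
        Reaction("first", q["k_unbind_b"], (5,), (0, 0, 0, +1, +1, -1), name="unbind_back"),
        Reaction("first", q["k_cat_b"], (5,), (0, +1, 0, 0, +1, -1), name="cat_back"),
    ]
    x0 = [q["n_enzyme"], q["n_substrate"], 0, 0, q["n_enzyme"], 0]
    channels: list[NoiseChannel] = []

    if variant == "noise_free":
        pass
    elif variant == "bounded_noise":
        channels = [
            NoiseChannel(
                "sine_wiener", amplitude=q["noise_B"], tau=q["noise_tau"],
                name="binding_noise",
            )
        ]
    elif variant == "with_F":
        species += ["F", "E2F"]
        reactions = [
            Reaction(r.order, r.rate_constant, r.reactants,
                     tuple(r.stoich) + (0, 0), name=r.name)
            for r in reactions
        ]
        z6 = (0, 0, 0, 0, 0, 0)
        reactions += [
            Reaction("zeroth", q["k_F_synth"], (), z6 + (+1, 0), name="F_synth"),
            Reaction("first", q["k_F_deg"], (6,), z6 + (-1, 0), name="F_deg"),
            Reaction("hetero", q["k_F_bind"], (4, 6),
                     (0, 0, 0, 0, -1, 0, -1, +1), name="F_bind"),
            Reaction("first", q["k_F_unbind"], (7,),
                     (0, 0, 0, 0, +1, 0, +1, -1), name="F_unbind"),
        ]
        x0 += [round(q["k_F_synth"] / q["k_F_deg"]), 0]
    else:
        raise NetworkConfigError(f"unknown futile-cycle variant {variant!r}")
    return Fixture(
        name="futile_cycle",
        variant=variant,
        network=ReactionNetwork(species, reactions),
        channels=channels,
        x0=np.asarray(x0),
        parameters=q,
        provenance={"structure": "published-model", "all numeric values": "repo-chosen"},
    )


# ---------------------------------------------------------------------------
# Toggle switch
# ---------------------------------------------------------------------------

#: Repo-chosen defaults for the two-gene mutual-repression switch.  The free
#: (unrepressed) steady state is ~5 mRNA and ~50 protein copies; repression
#: by a winning protein reduces synthesis ~180-fold, so the switch is
#: strongly bistable on the simulated horizon.  The initial condition gives
#: gene b a small head start, as in an asymmetrically induced cell.
TOGGLE_DEFAULTS = {
    "k_synth": 0.5,    # maximal mRNA synthesis (per minute)
    "k_transl": 1.0,   # translation per mRNA
    "k_deg_m": 0.1,    # mRNA degradation
    "k_deg_p": 0.1,    # protein degradation
    "K_a": 0.25,       # repressor association constant
    "m_sites": 2,      # regulatory sites that must all be free
    "mRNA_b0": 3,      # initial mRNA copies of gene b (head start)
}


#: Autocorrelation-time grid (minutes, slowest first) for the noise-speed
#: scan of the switch.  Spans the steep part of the response: noise slower
#: than the ~10-minute protein lifetime opens escape windows for the
#: repressed gene, faster noise is filtered out.
TOGGLE_TAU_SCAN = (30.0, 15.0, 7.5, 3.75)


def _p_free(P_other: float, K_a: float, m: int) -> float:
    """Probability that all m regulatory sites are free of repressor."""
    return (1.0 + K_a * P_other) ** (-m)


def build_toggle_switch(
    mode: str = "sine_wiener",
    params: Optional[dict] = None,
    intensity: float = 0.25,
    timescale: float = 60.0,
) -> Fixture:
    """Two mutually repressing genes with perturbed synthesis.

    Species (mRNA_a, mRNA_b, P_A, P_B).  Synthesis of each mRNA has the
    generalized propensity ``k_synth * w(t) * (1 + K_a * P_other)^(-m)``:
    both genes share one perturbation channel ``w = 1 + zeta``.

    ``mode="periodic"``: ``zeta(t) = intensity * sin(2 pi t / timescale)``
    (deterministic sinusoid of period ``timescale``).
    ``mode="sine_wiener"``: zeta a Sine-Wiener noise with amplitude
    ``intensity`` and autocorrelation time ``timescale``.
    ``mode="none"``: unperturbed switch (w = 1).
    """
    q = dict(TOGGLE_DEFAULTS)
    if params:
        q.update(params)
    m = int(q["m_sites"])
    if m < 1:
        raise NetworkConfigError("number of regulatory sites m must be >= 1")
    ks, kp = q["k_synth"], q["k_transl"]
    kdm, kdp = q["k_deg_m"], q["k_deg_p"]
    Ka = q["K_a"]
    species = ["mRNA_a", "mRNA_b", "P_A", "P_B"]

    def synth(other_protein_index):
        def fn(counts, zeta, t, _i=other_protein_index):
            w = 1.0 + (zeta[0] if zeta.size else 0.0)
            if w < 0.0:
                w = 0.0
            return ks * w * _p_free(counts[_i], Ka, m)

        return fn

    reactions = [
        Reaction("generalized", stoich=(+1, 0, 0, 0),
                 propensity_fn=synth(3), noise_channel=0 if mode != "none" else None,
                 name="synth_a"),
        Reaction("generalized", stoich=(0, +1, 0, 0),
                 propensity_fn=synth(2), noise_channel=0 if mode != "none" else None,
                 name="synth_b"),
        Reaction("first", kp, (0,), (0, 0, +1, 0), name="transl_a"),
        Reaction("first", kp, (1,), (0, 0, 0, +1), name="transl_b"),
        Reaction("first", kdm, (0,), (-1, 0, 0, 0), name="deg_mRNA_a"),
        Reaction("first", kdm, (1,), (0, -1, 0, 0), name="deg_mRNA_b"),
        Reaction("first", kdp, (2,), (0, 0, -1, 0), name="deg_P_A"),
        Reaction("first", kdp, (3,), (0, 0, 0, -1), name="deg_P_B"),
    ]
    if mode == "periodic":
        channels = [
            NoiseChannel("deterministic_periodic", amplitude=intensity,
                         tau=timescale, name="sinusoid")
        ]
    elif mode == "sine_wiener":
        channels = [
            NoiseChannel("sine_wiener", amplitude=intensity, tau=timescale,
                         name="synthesis_noise")
        ]
    elif mode == "none":
        channels = []
    else:
        raise NetworkConfigError(f"unknown toggle mode {mode!r}")
    x0 = np.array([0, int(q["mRNA_b0"]), 0, 0])
    return Fixture(
        name="toggle_switch",
        variant=mode,
        network=ReactionNetwork(species, reactions),
        channels=channels,
        x0=x0,
        parameters={**q, "intensity": intensity, "timescale": timescale},
        provenance={"structure": "published-model",
                    "repression form (1+K_a*P)^-m": "repo-chosen",
                    "all numeric values": "repo-chosen"},
    )


def list_fixtures() -> list[tuple[str, tuple[str, ...]]]:
    """Names and variants of the built-in case studies."""
    return [
        ("esp", ("exact", "mm_reduced")),
        ("futile_cycle", ("noise_free", "with_F", "bounded_noise")),
        ("toggle_switch", ("periodic", "sine_wiener", "none")),
    ]
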