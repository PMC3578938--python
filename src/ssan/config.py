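"""Model configuration: a human-editable YAML dialect and file writers.

No community standard covers reaction networks with bounded-noise-modulated
rates, so the package defines one canonical schema (documented in the
README).  A config round-trips losslessly: ``parse -> emit -> parse`` yields
an identical structure.  Two non-mass-action reaction kinds are expressible:
``michaelis_menten`` (the quasi-steady-state reduction, with optional noise
bindings on its three underlying rates) and ``repressed_synthesis`` (the
toggle-switch synthesis law).

Output files are written atomically (temp file + rename), so an error never
leaves a partial file behind.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .case_studies import Fixture, _p_free
from .engine import SimulationConfig, Trajectory
from .network import Reaction, ReactionNetwork
from .noise import NoiseChannel
from .qssa import MMParameters, mm_propensity, noisy_michaelis_constant

__all__ = [
    "ModelConfig",
    "ConfigError",
    "parse_config",
    "emit_config",
    "fixture_to_config",
    "write_trajectory_tsv",
    "write_matrix_tsv",
    "atomic_write_text",
]


class ConfigError(ValueError):
    """Schema violation; the message names the offending location."""


_TOP_KEYS = {"species", "initial", "reactions", "noise_channels", "simulation", "analysis"}
_RXN_KEYS = {"name", "order", "kind", "rate", "reactants", "products", "noise",
             "k1", "k_minus1", "k2", "E_total", "k_synth", "K_a", "m_sites",
             "repressor", "bindings"}
_CHAN_KEYS = {"name", "kind", "amplitude", "tau", "granularity"}
_SIM_KEYS = {"t0", "T", "record_points", "n_runs", "base_seed", "max_events"}
_ANA_KEYS = {"densities_at", "density_vs_time", "count_modes"}


@dataclass
class ModelConfig:
    """Parsed, validated model configuration."""

    species: list[str]
    initial: dict[str, int]
    reactions: list[dict]
    noise_channels: list[dict] = field(default_factory=list)
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    # ----- construction of runtime objects ---------------------------------

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.noise_channels):
            if ch["name"] == name:
                return i
        raise ConfigError(f"undeclared noise channel {name!r}")

    def build_channels(self) -> list[NoiseChannel]:
        return [
            NoiseChannel(
                kind=ch["kind"],
                amplitude=float(ch.get("amplitude", 0.5)),
                tau=float(ch.get("tau", 1.0)),
                granularity=ch.get("granularity"),
                name=ch["name"],
            )
            for ch in self.noise_channels
        ]

    def build_network(self) -> ReactionNetwork:
        n = len(self.species)
        sidx = {s: i for i, s in enumerate(self.species)}
        reactions = []
        for r in self.reactions:
            kind = r.get("kind", "mass_action")
            name = r.get("name", "")
            if kind == "mass_action":
                reactions.append(self._mass_action(r, sidx, n))
            elif kind == "michaelis_menten":
                reactions.append(self._michaelis(r, sidx, n))
            elif kind == "repressed_synthesis":
                reactions.append(self._repressed(r, sidx, n))
            else:
                raise ConfigError(f"reaction {name!r}: unknown kind {kind!r}")
        return ReactionNetwork(list(self.species), reactions)

    def initial_counts(self) -> np.ndarray:
        return np.array([int(self.initial.get(s, 0)) for s in self.species])

    def simulation_config(self, seed: Optional[int] = None) -> SimulationConfig:
        sim = self.simulation
        t0 = float(sim.get("t0", 0.0))
        T = float(sim.get("T", 10.0))
        npts = int(sim.get("record_points", 101))
        return SimulationConfig(
            t0=t0, T=T, record_grid=np.linspace(t0, T, npts),
            rng_seed=int(seed if seed is not None else sim.get("base_seed", 0)),
            max_events=int(sim.get("max_events", 50_000_000)),
        )

    # ----- per-kind reaction builders --------------------------------------

    def _stoich(self, r, sidx, n):
        nu = [0] * n
        for s in r.get("reactants", []):
            if s not in sidx:
                raise ConfigError(f"reaction {r.get('name')!r}: unknown species {s!r}")
            nu[sidx[s]] -= 1
        for s in r.get("products", []):
            if s not in sidx:
                raise ConfigError(f"reaction {r.get('name')!r}: unknown species {s!r}")
            nu[sidx[s]] += 1
        return tuple(nu)

    def _chan(self, r):
        if "noise" not in r or r["noise"] is None:
            return None
        try:
            return self.channel_index(r["noise"])
        except ConfigError as exc:
            raise ConfigError(f"reaction {r.get('name')!r}: {exc}") from None

    def _mass_action(self, r, sidx, n):
        reactants = [sidx[s] for s in r.get("reactants", [])]
        order = r.get("order")
        if order is None:  # infer from reactant multiset
            if len(reactants) == 0:
                order = "zeroth"
            elif len(reactants) == 1:
                order = "first"
            elif len(reactants) == 2:
                order = "dimerization" if reactants[0] == reactants[1] else "hetero"
            else:
                raise ConfigError(
                    f"reaction {r.get('name')!r}: more than two reactants"
                )
        ridx = tuple(dict.fromkeys(reactants)) if order == "dimerization" else tuple(reactants)
        return Reaction(
            order=order, rate_constant=float(r["rate"]), reactants=ridx,
            stoich=self._stoich(r, sidx, n), noise_channel=self._chan(r),
            name=r.get("name", ""),
        )

    def _michaelis(self, r, sidx, n):
        p = MMParameters(
            k1=float(r["k1"]), k_minus1=float(r["k_minus1"]), k2=float(r["k2"]),
            E_total=int(r["E_total"]), S0=0,
        )
        bindings = {
            rate: self.channel_index(chname)
            for rate, chname in (r.get("bindings") or {}).items()
        }
        sub = sidx[r["reactants"][0]]

        def fn(counts, zeta, t, _p=p, _b=bindings, _s=sub):
            km = noisy_michaelis_constant(_p, zeta, _b)
            return mm_propensity(counts[_s], _p, km)

        return Reaction(
            order="generalized", reactants=(sub,), stoich=self._stoich(r, sidx, n),
            propensity_fn=fn, name=r.get("name", ""),
        )

    def _repressed(self, r, sidx, n):
        rep = sidx[r["repressor"]]
        ks, Ka, m = float(r["k_synth"]), float(r["K_a"]), int(r.get("m_sites", 2))
        chan = self._chan(r)

        def fn(counts, zeta, t, _rep=rep, _c=chan):
            w = 1.0 if _c is None or not zeta.size else max(1.0 + zeta[_c], 0.0)
            return ks * w * _p_free(counts[_rep], Ka, m)

        return Reaction(
            order="generalized", stoich=self._stoich(r, sidx, n),
            propensity_fn=fn, noise_channel=chan, name=r.get("name", ""),
        )

    def to_dict(self) -> dict:
        out = {
            "species": list(self.species),
            "initial": dict(self.initial),
            "reactions": [dict(r) for r in self.reactions],
        }
        if self.noise_channels:
            out["noise_channels"] = [dict(c) for c in self.noise_channels]
        if self.simulation:
            out["simulation"] = dict(self.simulation)
        if self.analysis:
            out["analysis"] = dict(self.analysis)
        return out


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def parse_config(text: str) -> ModelConfig:
    """Parse and schema-validate a YAML model configuration."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "species" not in raw or not raw["species"]:
        raise ConfigError("top level: 'species' list is required")
    for i, r in enumerate(raw.get("reactions", [])):
        _check_keys(r, _RXN_KEYS, f"reactions[{i}] ({r.get('name', '?')})")
    for i, c in enumerate(raw.get("noise_channels", [])):
        _check_keys(c, _CHAN_KEYS, f"noise_channels[{i}]")
        if "name" not in c:
            raise ConfigError(f"noise_channels[{i}]: 'name' is required")
    _check_keys(raw.get("simulation", {}), _SIM_KEYS, "simulation")
    _check_keys(raw.get("analysis", {}), _ANA_KEYS, "analysis")
    cfg = ModelConfig(
        species=list(raw["species"]),
        initial=dict(raw.get("initial", {})),
        reactions=[dict(r) for r in raw.get("reactions", [])],
        noise_channels=[dict(c) for c in raw.get("noise_channels", [])],
        simulation=dict(raw.get("simulation", {})),
        analysis=dict(raw.get("analysis", {})),
    )
    for s in cfg.initial:
        if s not in cfg.species:
            raise ConfigError(f"initial: unknown species {s!r}")
    cfg.build_network()  # full structural validation
    cfg.build_channels()
    return cfg


def emit_config(cfg: ModelConfig) -> str:
    """Serialize back to canonical YAML (stable key order)."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------


def fixture_to_config(fixture: Fixture, simulation: Optional[dict] = None) -> ModelConfig:
    """Express a built-in case-study fixture in the generic config schema."""
    net = fixture.network
    chans = [
        {"name": ch.name or f"chan{i}", "kind": ch.kind,
         "amplitude": ch.amplitude, "tau": ch.tau}
        for i, ch in enumerate(fixture.channels)
    ]

    def chan_name(idx):
        return None if idx is None else chans[idx]["name"]

    reactions = []
    prm = fixture.parameters
    for j, r in enumerate(net.reactions):
        nu = net.stoichiometry[:, j]
        if r.order != "generalized":
            reactants = []
            for i in r.reactants:
                reactants.append(net.species_names[i])
            if r.order == "dimerization":
                reactants = reactants * 2
            products = []
            consumed = {i: 0 for i in range(net.n_species)}
            for s in reactants:
                consumed[net.species_names.index(s)] += 1
            for i, d in enumerate(nu):
                mult = d + consumed[i]
                products.extend([net.species_names[i]] * int(mult))
            entry = {"name": r.name, "kind": "mass_action",
                     "rate": r.rate_constant, "reactants": reactants,
                     "products": products}
            if r.noise_channel is not None:
                entry["noise"] = chan_name(r.noise_channel)
            reactions.append(entry)
        elif fixture.name == "esp":
            reactions.append({
                "name": r.name, "kind": "michaelis_menten",
                "k1": prm["k1"], "k_minus1": prm["k_minus1"], "k2": prm["k2"],
                "E_total": prm["E_total"],
                "reactants": ["S"], "products": ["P"],
                "bindings": {
                    rate: chans[i]["name"]
                    for rate, i in prm.get("bindings", {}).items()
                },
            })
        elif fixture.name == "toggle_switch":
            product = net.species_names[int(np.argmax(nu))]
            repressor = "P_B" if product == "mRNA_a" else "P_A"
            entry = {"name": r.name, "kind": "repressed_synthesis",
                     "k_synth": prm["k_synth"], "K_a": prm["K_a"],
                     "m_sites": prm["m_sites"], "repressor": repressor,
                     "products": [product]}
            if r.noise_channel is not None:
                entry["noise"] = chan_name(r.noise_channel)
            reactions.append(entry)
        else:
            raise ConfigError(
                f"fixture {fixture.name!r} has a non-exportable generalized reaction"
            )
    cfg = ModelConfig(
        species=list(net.species_names),
        initial={s: int(v) for s, v in zip(net.species_names, fixture.x0)},
        reactions=reactions,
        noise_channels=chans,
        simulation=dict(simulation or {}),
    )
    return cfg


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def atomic_write_text(path: str, text: str) -> None:
    """Write via a temp file in the same directory + atomic rename."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trajectory_tsv(path: str, traj: Trajectory, channel_names: Sequence[str] = ()) -> None:
    """Tab-separated (time, species counts..., noise values...) on the record grid."""
    header = ["time"] + list(traj.species_names) + [
        f"noise_{name}" for name in channel_names
    ]
    lines = ["\t".join(header)]
    for i, t in enumerate(traj.record_times):
        row = [f"{t:.10g}"] + [str(int(v)) for v in traj.counts[i]]
        row += [f"{traj.noise[i, c]:.10g}" for c in range(len(channel_names))]
        lines.append("\t".join(row))
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_matrix_tsv(path: str, row_labels, col_labels, matrix, corner="count\\time") -> None:
    """Tab-separated matrix with header row and row labels (heatmap export)."""
    lines = ["\t".join([corner] + [f"{c:.10g}" for c in col_labels])]
    for lab, row in zip(row_labels, np.asarray(matrix)):
        lines.append("\t".join([f"{lab:.10g}" if isinstance(lab, float) else str(lab)]
                              + [f"{v:.10g}" for v in row]))
    atomic_write_text(path, "\n".join(lines) + "\n")
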