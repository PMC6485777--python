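"""The planarian anterior-posterior regulatory network.

Nine interacting factors control head/tail identity:

* **Hh** (Hedgehog) -- produced in nerve somata (neural, production weighted
  by G) and carried toward the posterior by kinesin (+alpha).
* **Wnt** (Wnt1/Wnt11 combined) -- induced by Hh and by a basal channel, both
  gated by active Ptc (Hh inactivates Ptc, so Wnt expression opens up where
  Hh accumulates); degraded at the anterior by Notum.
* **bcat** (beta-catenin) -- constitutively produced; removed by an
  APC-dependent destruction complex whose action is Hill-inhibited by Wnt
  and, in a parallel channel, by cAMP.  Posterior/tail determinant.
* **ERK** -- constitutively produced but Hill-inhibited by bcat; anterior /
  head determinant.
* **NRF** (Notum Regulating Factor) -- induced by bcat in nerve somata and
  hauled to the anterior by dynein (-alpha).
* **Notum** -- induced by NRF, hence appearing at anterior-facing wounds,
  where it clears Wnt.
* **cAMP** -- uniform second messenger stabilizing bcat (inhibits one
  destruction channel); the entry point of the serotonin/dopamine
  pharmacology.
* **Ptc**, **APC** -- constitutive gate/scaffold species held at unit level.

Concentration units are relative ("model nM"); rates are per second.  The
default parameterization is constrained by the qualitative phenotype table
(which intervention yields which heteromorphosis class) and by the wound
sigmoid midpoints of the Markov outcome model (ERK ~ 0.75 at head-competent
wounds, bcat ~ 300 at tail-competent wounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

__all__ = [
    "DecayChannel",
    "GrowthChannel",
    "Intervention",
    "NetworkModel",
    "RegulatoryTerm",
    "SpeciesSpec",
    "default_network",
    "intervention_catalog",
]

SPECIES_NAMES = ("Hh", "Wnt", "bcat", "ERK", "Notum", "NRF", "cAMP", "Ptc", "APC")

ROLES = (
    "growth-activator",
    "growth-inhibitor",
    "decay-activator",
    "decay-inhibitor",
)


@dataclass
class RegulatoryTerm:
    """One Hill factor: activator ``(C/K)^n / (1 + (C/K)^n)`` or inhibitor
    ``1 / (1 + (C/K)^n)``.

    An optional gate species first converts the regulator to its active
    form: ``C_eff = C / (1 + (C_gate/K_gate)^n_gate)`` (used for Ptc, whose
    repression of Wnt is itself relieved by Hh).
    """

    regulator: str
    K: float
    n: float
    role: str
    gate: str | None = None
    gate_K: float = 1.0
    gate_n: float = 2.0

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown regulatory role {self.role!r}")
        if self.K <= 0 or self.n <= 0:
            raise ValueError("Hill parameters K and n must be positive")


@dataclass
class GrowthChannel:
    name: str
    rate: float
    factors: list = dc_field(default_factory=list)


@dataclass
class DecayChannel:
    name: str
    rate: float
    factors: list = dc_field(default_factory=list)


@dataclass
class SpeciesSpec:
    """One network species with its transport and kinetic parameters."""

    name: str
    D: float = 0.0
    alpha: float = 0.0
    neural: bool = False
    initial: float = 0.0
    growth: list = dc_field(default_factory=list)
    decay: list = dc_field(default_factory=list)

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("diffusivity must be non-negative")


@dataclass
class Intervention:
    """Growth-rate multiplier on one species, applied during a schedule
    window (RNAi knockdowns use 0.0; pharmacology scales cAMP growth)."""

    label: str
    target: str
    multiplier: float
    schedule: str = "post_cut"  # "post_cut" | "full" | "partial"

    def __post_init__(self):
        if self.multiplier < 0:
            raise ValueError("growth multiplier must be non-negative")


class NetworkModel:
    """Species collection plus parameter access by dotted path."""

    def __init__(self, species: list[SpeciesSpec]):
        self.species = list(species)
        self.by_name = {s.name: s for s in self.species}
        for s in self.species:
            for ch in list(s.growth) + list(s.decay):
                for t in ch.factors:
                    if t.regulator not in self.by_name:
                        raise ValueError(
                            f"{s.name}: unknown regulator {t.regulator!r}"
                        )
                    if t.gate is not None and t.gate not in self.by_name:
                        raise ValueError(
                            f"{s.name}: unknown gate species {t.gate!r}"
                        )

    @property
    def d_max(self) -> float:
        return max(s.D for s in self.species)

    def initial_state(self, n_cells: int) -> dict:
        return {
            s.name: np.full(n_cells, float(s.initial)) for s in self.species
        }

    # -- flat parameter access (sensitivity analysis, config round-trip) ---

    def _locate(self, path: str):
        parts = path.split(".")
        spec = self.by_name[parts[0]]
        if len(parts) == 2:
            return spec, parts[1]
        kind, chan = parts[1], parts[2]
        channels = spec.growth if kind == "growth" else spec.decay
        ch = next(c for c in channels if c.name == chan)
        if len(parts) == 4 and parts[3] == "rate":
            return ch, "rate"
        term = next(t for t in ch.factors if t.regulator == parts[3])
        return term, parts[4]

    def get_param(self, path: str) -> float:
        obj, attr = self._locate(path)
        return getattr(obj, attr)

    def set_param(self, path: str, value: float):
        obj, attr = self._locate(path)
        setattr(obj, attr, value)

    def param_names(self) -> list[str]:
        names = []
        for s in self.species:
            for attr in ("D", "alpha", "initial"):
                names.append(f"{s.name}.{attr}")
            for kind, channels in (("growth", s.growth), ("decay", s.decay)):
                for ch in channels:
                    names.append(f"{s.name}.{kind}.{ch.name}.rate")
                    for t in ch.factors:
                        names.append(f"{s.name}.{kind}.{ch.name}.{t.regulator}.K")
                        names.append(f"{s.name}.{kind}.{ch.name}.{t.regulator}.n")
        return names

    def copy(self) -> "NetworkModel":
        return NetworkModel.from_dict(self.to_dict())

    # -- config round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        def term_d(t: RegulatoryTerm):
            d = {"regulator": t.regulator, "K": t.K, "n": t.n, "role": t.role}
            if t.gate is not None:
                d.update(gate=t.gate, gate_K=t.gate_K, gate_n=t.gate_n)
            return d

        out = {"species": []}
        for s in self.species:
            out["species"].append(
                {
                    "name": s.name,
                    "D": s.D,
                    "alpha": s.alpha,
                    "neural": s.neural,
                    "initial": s.initial,
                    "growth": [
                        {
                            "name": c.name,
                            "rate": c.rate,
                            "factors": [term_d(t) for t in c.factors],
                        }
                        for c in s.growth
                    ],
                    "decay": [
                        {
                            "name": c.name,
                            "rate": c.rate,
                            "factors": [term_d(t) for t in c.factors],
                        }
                        for c in s.decay
                    ],
                }
            )
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        species = []
        for sd in d["species"]:
            def chans(key, C):
                return [
                    C(
                        name=cd["name"],
                        rate=cd["rate"],
                        factors=[RegulatoryTerm(**td) for td in cd["factors"]],
                    )
                    for cd in sd.get(key, [])
                ]

            species.append(
                SpeciesSpec(
                    name=sd["name"],
                    D=sd.get("D", 0.0),
                    alpha=sd.get("alpha", 0.0),
                    neural=sd.get("neural", False),
                    initial=sd.get("initial", 0.0),
                    growth=chans("growth", GrowthChannel),
                    decay=chans("decay", DecayChannel),
                )
            )
        return cls(species)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _act(reg, K, n=2.0, **kw):
    return RegulatoryTerm(reg, K, n, "growth-activator", **kw)


def _inh(reg, K, n=2.0, **kw):
    return RegulatoryTerm(reg, K, n, "growth-inhibitor", **kw)


def _dact(reg, K, n=2.0, **kw):
    return RegulatoryTerm(reg, K, n, "decay-activator", **kw)


def _dinh(reg, K, n=2.0, **kw):
    return RegulatoryTerm(reg, K, n, "decay-inhibitor", **kw)


def default_network() -> NetworkModel:
    """Default planarian AP-axis network parameterization.

    Transport coefficients sit in the fast-axonal-transport range
    (|alpha| ~ 3e-7 m/s at unit field strength); diffusivities are bounded by
    D_max = 1.5e-11 m^2/s.  bcat runs on a hundreds-of-nM scale to interface
    with the Markov tail sigmoid (midpoint 300 nM); ERK on an O(1) nM scale
    (head sigmoid midpoint 0.75 nM); the remaining factors are O(1).
    """
    species = [
        SpeciesSpec(
            "Hh",
            D=1.5e-11,
            alpha=+4.0e-7,
            neural=True,
            growth=[GrowthChannel("neural", 2.0e-4)],
            decay=[DecayChannel("basal", 3.0e-5)],
        ),
        SpeciesSpec(
            "Wnt",
            D=1.0e-11,
            growth=[
                GrowthChannel(
                    "basal",
                    8.5e-4,
                    [_inh("Ptc", 0.2, 2.0, gate="Hh", gate_K=4.0, gate_n=2.0)],
                ),
                GrowthChannel(
                    "hedgehog",
                    2.3e-3,
                    [_act("Hh", 8.0, 2.0)],
                ),
            ],
            decay=[
                DecayChannel("basal", 6.0e-5),
                DecayChannel("notum", 2.0e-4, [_dact("Notum", 0.3, 2.0)]),
            ],
        ),
        SpeciesSpec(
            "bcat",
            D=1.0e-12,
            growth=[GrowthChannel("basal", 8.0e-3)],
            decay=[
                DecayChannel("basal", 1.16e-5),
                DecayChannel(
                    "destruction",
                    5.0e-2,
                    [
                        _dact("APC", 1.0, 2.0),
                        _dinh("Wnt", 0.35, 2.0),
                        _dinh("cAMP", 0.4, 4.0),
                    ],
                ),
                DecayChannel(
                    "destruction_camp_independent",
                    2.4e-4,
                    [_dact("APC", 1.0, 2.0), _dinh("Wnt", 0.35, 2.0)],
                ),
            ],
        ),
        SpeciesSpec(
            "ERK",
            D=1.0e-11,
            growth=[GrowthChannel("basal", 2.0e-4, [_inh("bcat", 25.0, 4.0)])],
            decay=[DecayChannel("basal", 1.0e-4)],
        ),
        SpeciesSpec(
            "Notum",
            D=1.0e-11,
            growth=[GrowthChannel("nrf", 1.0e-4, [_act("NRF", 0.1, 2.0)])],
            decay=[DecayChannel("basal", 1.0e-4)],
        ),
        SpeciesSpec(
            "NRF",
            D=1.5e-11,
            alpha=-4.0e-7,
            neural=True,
            growth=[GrowthChannel("neural", 1.0e-4, [_act("bcat", 150.0, 2.0)])],
            decay=[DecayChannel("basal", 4.0e-5)],
        ),
        SpeciesSpec(
            "cAMP",
            D=1.0e-11,
            initial=1.0,
            growth=[GrowthChannel("basal", 1.0e-4)],
            decay=[DecayChannel("basal", 1.0e-4)],
        ),
        SpeciesSpec(
            "Ptc",
            growth=[GrowthChannel("basal", 1.0e-4)],
            decay=[DecayChannel("basal", 1.0e-4)],
        ),
        SpeciesSpec(
            "APC",
            growth=[GrowthChannel("basal", 1.0e-4)],
            decay=[DecayChannel("basal", 1.0e-4)],
        ),
    ]
    return NetworkModel(species)


def intervention_catalog() -> dict[str, Intervention]:
    """The modeled RNAi and pharmacological perturbations.

    RNAi sets the target's growth to zero; cAMP-lowering agents (adenylyl
    cyclase inhibition, D2R agonism, 5HT7R-like inhibition) scale cAMP
    growth by 0.25; cAMP-raising agents (phosphodiesterase inhibition,
    serotonin) scale it by 5; U0126 blocks ERK synthesis.
    """
    entries = [
        Intervention("RNAi-Wnt", "Wnt", 0.0),
        Intervention("RNAi-Hh", "Hh", 0.0),
        Intervention("RNAi-Ptc", "Ptc", 0.0),
        Intervention("RNAi-APC", "APC", 0.0),
        Intervention("RNAi-Notum", "Notum", 0.0),
        Intervention("RNAi-bcat-full", "bcat", 0.0, schedule="full"),
        Intervention("RNAi-bcat-partial", "bcat", 0.0, schedule="partial"),
        Intervention("U0126", "ERK", 0.0),
        Intervention("MDL12330A", "cAMP", 0.25),
        Intervention("dopamine", "cAMP", 0.25),
        Intervention("bromocriptine", "cAMP", 0.25),
        Intervention("IBMX", "cAMP", 5.0),
        Intervention("serotonin", "cAMP", 5.0),
    ]
    return {e.label: e for e in entries}
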