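"""Reaction network for cytosolic copper handling in budding yeast.

The canonical model tracks ten cytosolic components — the transcription
factors MAC and ACE (apo and holo), metallothionein CUP (apo/holo), a
lumped pool of other copper proteins OTH (apo/holo), the importer CTR,
and the labile low-molecular-mass copper pool CU — coupled by 25
reactions: 5 biosynthesis, 2 import, 4 metallation, 4 demetallation and
10 growth-dilution reactions.  Nutrient COPPER is a boundary condition,
not a state variable; growth dilution is the only removal process.

All concentrations are in μM and all times in minutes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RateLaw",
    "Component",
    "Reaction",
    "ReferenceState",
    "ReactionNetwork",
    "build_canonical_network",
    "stoichiometric_matrix",
    "evaluate_rate",
    "cu_weight_vector",
    "COMPONENTS",
    "REACTIONS",
    "ALPHA_CELL",
]

#: Exponential growth rate of the cell culture (per minute).
ALPHA_CELL = 0.0033

#: Canonical component order (apo before holo, CTR and CU last).
COMPONENTS = ("aMAC", "MAC", "aACE", "ACE", "aCUP", "CUP", "aOTH", "OTH", "CTR", "CU")

#: Canonical reaction order: biosynthesis, import, metallation,
#: demetallation, dilution.
REACTIONS = (
    "BAMAC", "BAACE", "BACUP", "BAOTH", "BCTR",
    "CUIN1", "CUIN2",
    "MMACF", "MACEF", "MCUPF", "MOTHF",
    "MMACR", "MACER", "MCUPR", "MOTHR",
    "DAMAC", "DMAC", "DAACE", "DACE", "DACUP",
    "DCUP", "DAOTH", "DOTH", "DCTR", "DCU",
)

#: Copper ions carried by the holo form of each protein.
CU_STOICHIOMETRY = {"MAC": 4, "ACE": 4, "CUP": 8, "OTH": 1, "CU": 1}

#: Species whose concentration the homeostat holds steady; everything
#: else does the regulating.
REGULATED = frozenset({"CU", "aOTH", "OTH"})


class RateLaw(enum.Enum):
    CONSTANT_BIOSYNTHESIS = "constant_biosynthesis"
    CATALYZED_BIOSYNTHESIS = "catalyzed_biosynthesis"
    MICHAELIS_MENTEN_IMPORT = "michaelis_menten_import"
    MASS_ACTION_METALLATION = "mass_action_metallation"
    FIRST_ORDER_DEMETALLATION = "first_order_demetallation"
    FIRST_ORDER_DILUTION = "first_order_dilution"


@dataclass(frozen=True)
class Component:
    name: str
    role: str  # "regulated" or "regulating"
    cu_stoichiometry: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("regulated", "regulating"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.cu_stoichiometry < 0:
            raise ValueError("cu_stoichiometry must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry maps plus a rate-law descriptor.

    ``parameters`` may hold ``km`` (μM, Michaelis constant for imports),
    ``cooperativity`` (exponent on the normalized CU factor of
    metallation reactions) and ``senses`` ("CU" or "COPPER" for the
    reactions whose rate constant is augmented with a logistic switch).
    """

    name: str
    substrates: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    catalyst: str | None = None
    rate_law: RateLaw = RateLaw.CONSTANT_BIOSYNTHESIS
    parameters: dict = field(default_factory=dict)

    @property
    def senses(self) -> str | None:
        return self.parameters.get("senses")


@dataclass(frozen=True)
class ReferenceState:
    """Reference (mid-titration) steady state used to normalize rate laws.

    ``concentrations`` maps each of the ten components to its reference
    steady-state concentration in μM; every entry must be positive since
    they appear as denominators.  ``alpha_cell`` is the exponential
    growth rate in min⁻¹ and ``copper_by_condition`` maps titration
    labels to the effective nutrient COPPER in μM.
    """

    concentrations: dict[str, float]
    alpha_cell: float = ALPHA_CELL
    copper_by_condition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COMPONENTS) - set(self.concentrations)
        if missing:
            raise ValueError(f"reference state missing components: {sorted(missing)}")
        for name, c in self.concentrations.items():
            if not c > 0:
                raise ValueError(f"reference concentration for {name} must be > 0")


class ReactionNetwork:
    """Immutable collection of components and reactions with validation."""

    def __init__(self, components: list[Component], reactions: list[Reaction]):
        self.components = tuple(components)
        self.reactions = tuple(reactions)
        self._component_index = {c.name: i for i, c in enumerate(self.components)}
        self._reaction_index = {r.name: i for i, r in enumerate(self.reactions)}
        self._validate()

    def _validate(self) -> None:
        if len(self._component_index) != len(self.components):
            raise ValueError("duplicate component names")
        if len(self._reaction_index) != len(self.reactions):
            raise ValueError("duplicate reaction names")
        for r in self.reactions:
            for species in list(r.substrates) + list(r.products):
                if species not in self._component_index:
                    raise ValueError(f"reaction {r.name} references unknown {species}")
            if r.catalyst is not None and r.catalyst not in self._component_index:
                raise ValueError(f"reaction {r.name} has unknown catalyst {r.catalyst}")
            if r.rate_law is RateLaw.FIRST_ORDER_DILUTION:
                if len(r.substrates) != 1 or r.products:
                    raise ValueError(f"dilution {r.name} must have one substrate, no products")

    def component(self, name: str) -> Component:
        return self.components[self._component_index[name]]

    def reaction(self, name: str) -> Reaction:
        return self.reactions[self._reaction_index[name]]

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def reaction_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.reactions)


def build_canonical_network() -> ReactionNetwork:
    """Assemble the canonical 10-component, 25-reaction network.

    CUIN1 is the CTR-catalyzed high-affinity import (Km = 2 μM); CUIN2
    the low-affinity MAC-independent import (Km = 35 μM).  BCTR is
    catalyzed by aMAC and BACUP by holo ACE.  BACUP, MCUPF and MOTHF
    carry a logistic augmentation sensing the labile pool CU, CUIN2 one
    sensing nutrient COPPER.  Metallation consumes 4, 4, 8 and 1 CU for
    MAC, ACE, CUP and OTH with rate-law cooperativity exponents 0.62,
    0.90, 1.1 and 1.0.
    """
    components = []
    for name in COMPONENTS:
        role = "regulated" if name in REGULATED else "regulating"
        components.append(Component(name, role, CU_STOICHIOMETRY.get(name, 0)))

    metallation_spec = {
        # holo name -> (apo, n_cu, cooperativity, senses)
        "MAC": ("aMAC", 4, 0.62, None),
        "ACE": ("aACE", 4, 0.90, None),
        "CUP": ("aCUP", 8, 1.1, "CU"),
        "OTH": ("aOTH", 1, 1.0, "CU"),
    }

    reactions = [
        Reaction("BAMAC", products={"aMAC": 1}, rate_law=RateLaw.CONSTANT_BIOSYNTHESIS),
        Reaction("BAACE", products={"aACE": 1}, rate_law=RateLaw.CONSTANT_BIOSYNTHESIS),
        Reaction("BACUP", products={"aCUP": 1}, catalyst="ACE",
                 rate_law=RateLaw.CATALYZED_BIOSYNTHESIS, parameters={"senses": "CU"}),
        Reaction("BAOTH", products={"aOTH": 1}, rate_law=RateLaw.CONSTANT_BIOSYNTHESIS),
        Reaction("BCTR", products={"CTR": 1}, catalyst="aMAC",
                 rate_law=RateLaw.CATALYZED_BIOSYNTHESIS),
        Reaction("CUIN1", products={"CU": 1}, catalyst="CTR",
                 rate_law=RateLaw.MICHAELIS_MENTEN_IMPORT, parameters={"km": 2.0}),
        Reaction("CUIN2", products={"CU": 1},
                 rate_law=RateLaw.MICHAELIS_MENTEN_IMPORT,
                 parameters={"km": 35.0, "senses": "COPPER"}),
    ]
    for holo, (apo, n_cu, coop, senses) in metallation_spec.items():
        params: dict = {"cooperativity": coop}
        if senses:
            params["senses"] = senses
        reactions.append(Reaction(
            f"M{holo}F", substrates={apo: 1, "CU": n_cu}, products={holo: 1},
            rate_law=RateLaw.MASS_ACTION_METALLATION, parameters=params))
    for holo, (apo, n_cu, _coop, _s) in metallation_spec.items():
        reactions.append(Reaction(
            f"M{holo}R", substrates={holo: 1}, products={apo: 1, "CU": n_cu},
            rate_law=RateLaw.FIRST_ORDER_DEMETALLATION))
    for name in COMPONENTS:
        # dilution names: aMAC -> DAMAC, MAC -> DMAC, ...
        reactions.append(Reaction(
            "D" + name.replace("a", "A", 1) if name.startswith("a") else "D" + name,
            substrates={name: 1}, rate_law=RateLaw.FIRST_ORDER_DILUTION))

    net = ReactionNetwork(components, reactions)
    assert net.reaction_names == REACTIONS, net.reaction_names
    return net


def stoichiometric_matrix(network: ReactionNetwork) -> pd.DataFrame:
    """Signed stoichiometric matrix S (components × reactions).

    S·R yields the vector of component concentration derivatives.
    Rows follow the network's component order, columns its reaction
    order; entries are integers.
    """
    S = pd.DataFrame(
        0,
        index=list(network.component_names),
        columns=list(network.reaction_names),
        dtype=int,
    )
    for r in network.reactions:
        for species, nu in r.substrates.items():
            S.loc[species, r.name] -= nu
        for species, nu in r.products.items():
            S.loc[species, r.name] += nu
    return S


def cu_weight_vector(network: ReactionNetwork) -> pd.Series:
    """Copper equivalents carried per μM of each component.

    The dot product of this vector with a concentration vector gives the
    total modelled cellular copper in μM.
    """
    return pd.Series(
        {c.name: float(c.cu_stoichiometry) for c in network.components},
        name="cu_equivalents",
    )


def _normalized(conc: float, ref: float) -> float:
    return conc / ref


def evaluate_rate(
    reaction: Reaction,
    state: dict[str, float],
    copper: float,
    ref: ReferenceState,
    k: float,
    logistic_factor: float = 1.0,
) -> float:
    """Evaluate one reaction rate (μM/min) at a given state.

    Every concentration factor is normalized by its reference value so
    that at the reference state the rate reduces to ``k`` (times the
    Michaelis–Menten saturation for imports and the logistic factor for
    regulated reactions).  ``logistic_factor`` multiplies the rate of
    reactions flagged as sensing CU or COPPER; pass 1 to evaluate the
    unaugmented law.
    """
    for name, c in state.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
    if copper < 0:
        raise ValueError("negative COPPER")

    law = reaction.rate_law
    rate = k
    if law is RateLaw.CONSTANT_BIOSYNTHESIS:
        pass
    elif law is RateLaw.CATALYZED_BIOSYNTHESIS:
        cat = reaction.catalyst
        rate *= _normalized(state[cat], ref.concentrations[cat])
    elif law is RateLaw.MICHAELIS_MENTEN_IMPORT:
        km = reaction.parameters["km"]
        rate *= copper / (km + copper)
        if reaction.catalyst is not None:
            cat = reaction.catalyst
            rate *= _normalized(state[cat], ref.concentrations[cat])
    elif law is RateLaw.MASS_ACTION_METALLATION:
        (apo,) = [s for s in reaction.substrates if s != "CU"]
        coop = reaction.parameters["cooperativity"]
        rate *= _normalized(state[apo], ref.concentrations[apo])
        rate *= _normalized(state["CU"], ref.concentrations["CU"]) ** coop
    elif law is RateLaw.FIRST_ORDER_DEMETALLATION:
        (holo,) = [s for s in reaction.substrates if s != "CU"]
        rate *= _normalized(state[holo], ref.concentrations[holo])
    elif law is RateLaw.FIRST_ORDER_DILUTION:
        (species,) = reaction.substrates
        rate *= _normalized(state[species], ref.concentrations[species])
    else:  # pragma: no cover
        raise NotImplementedError(law)

    if reaction.senses is not None:
        rate *= logistic_factor
    if math.isnan(rate):
        raise FloatingPointError(f"rate of {reaction.name} is NaN")
    return rate


def rate_law_factor(
    reaction: Reaction,
    state: dict[str, float],
    copper: float,
    ref: ReferenceState,
) -> float:
    """Product of normalized rate-law factors, excluding k and any logistic.

    Dividing a steady-state rate by this factor yields the apparent rate
    constant of the reaction at that state.
    """
    return evaluate_rate(reaction, state, copper, ref, k=1.0, logistic_factor=1.0)
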