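"""Serialization: network definitions, tabular exports, SBML.

The network round-trips through a YAML dialect listing components and
reactions with stoichiometries and rate-law parameters.  Tabular
products (titration inputs, condition tables, rate and rate-constant
tables, the pathway basis, trajectories and sweeps) are tab-separated
text.  SBML Level 3 export is available when python-libsbml is
installed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .calibration import LogisticParams, ParameterSet
from .dynamics import Trajectory
from .network import Component, RateLaw, Reaction, ReactionNetwork
from .pathways import PathwayBasis

__all__ = [
    "network_to_yaml",
    "network_from_yaml",
    "parameters_to_yaml",
    "parameters_from_yaml",
    "read_titration_tsv",
    "write_titration_tsv",
    "write_table_tsv",
    "write_pathway_basis_tsv",
    "write_trajectory_tsv",
    "network_to_sbml",
]

TITRATION_COLUMNS = ["condition", "COPPER_uM", "Cu_CUP_uM", "Cu_OTH_uM", "Cu_CU_uM"]


def network_to_yaml(network: ReactionNetwork, path: str | Path | None = None) -> str:
    doc = {
        "components": [
            {"name": c.name, "role": c.role, "cu_stoichiometry": c.cu_stoichiometry}
            for c in network.components
        ],
        "reactions": [
            {
                "name": r.name,
                "substrates": dict(r.substrates),
                "products": dict(r.products),
                "catalyst": r.catalyst,
                "rate_law": r.rate_law.value,
                "parameters": dict(r.parameters),
            }
            for r in network.reactions
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def network_from_yaml(source: str | Path) -> ReactionNetwork:
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    components = [
        Component(c["name"], c["role"], c.get("cu_stoichiometry", 0))
        for c in doc["components"]
    ]
    reactions = [
        Reaction(
            name=r["name"],
            substrates=dict(r.get("substrates") or {}),
            products=dict(r.get("products") or {}),
            catalyst=r.get("catalyst"),
            rate_law=RateLaw(r["rate_law"]),
            parameters=dict(r.get("parameters") or {}),
        )
        for r in doc["reactions"]
    ]
    return ReactionNetwork(components, reactions)


def parameters_to_yaml(params: ParameterSet, path: str | Path | None = None) -> str:
    doc = {
        "scalar_k": {k: float(v) for k, v in sorted(params.scalar_k.items())},
        "logistic": {
            name: {
                "k_invariant": lp.k_invariant,
                "sen_sp": lp.sen_sp,
                "n_sens": lp.n_sens,
                "sensed_species": lp.sensed_species,
            }
            for name, lp in sorted(params.logistic.items())
        },
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def parameters_from_yaml(source: str | Path) -> ParameterSet:
    text = Path(source).read_text() if isinstance(source, Path) else source
    doc = yaml.safe_load(text)
    return ParameterSet(
        scalar_k={k: float(v) for k, v in doc["scalar_k"].items()},
        logistic={
            name: LogisticParams(**spec) for name, spec in doc["logistic"].items()
        },
    )


def read_titration_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TITRATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"titration table missing columns: {missing}")
    return table


def write_titration_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def write_pathway_basis_tsv(W: PathwayBasis, path: str | Path) -> None:
    W.matrix.to_csv(path, sep="\t")


def write_trajectory_tsv(traj: Trajectory, path: str | Path) -> None:
    frame = traj.states.copy()
    frame.index.name = "time_min"
    frame.to_csv(path, sep="\t")


def network_to_sbml(network: ReactionNetwork, path: str | Path) -> None:
    """Export the network skeleton as an SBML Level 3 model.

    Requires python-libsbml.  Species and reactions carry their
    stoichiometries and modifier (catalyst) links; rate-law parameters
    are attached as annotations-free local parameters.
    """
    try:
        import libsbml
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "SBML export requires the optional python-libsbml package"
        ) from err

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel("copper_homeostasis")
    comp = model.createCompartment()
    comp.setId("cytosol")
    comp.setConstant(True)
    comp.setSize(1.0)
    for c in network.components:
        s = model.createSpecies()
        s.setId(c.name)
        s.setCompartment("cytosol")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
    for r in network.reactions:
        rxn = model.createReaction()
        rxn.setId(r.name)
        rxn.setReversible(False)
        for species, nu in r.substrates.items():
            ref = rxn.createReactant()
            ref.setSpecies(species)
            ref.setStoichiometry(float(nu))
            ref.setConstant(True)
        for species, nu in r.products.items():
            ref = rxn.createProduct()
            ref.setSpecies(species)
            ref.setStoichiometry(float(nu))
            ref.setConstant(True)
        if r.catalyst:
            mod = rxn.createModifier()
            mod.setSpecies(r.catalyst)
    libsbml.writeSBMLToFile(doc, str(path))
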