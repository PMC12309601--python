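"""Per-condition component concentrations from measured copper groups.

Chromatographic Cu measurements resolve cytosolic copper into three
groups — metallothionein-bound (CUP), other Cu proteins (OTH) and the
labile low-molecular-mass pool (CU).  Converting group copper into
protein concentrations requires the Cu stoichiometry of the protein and
its fractional occupancy:

    holo = [Cu]_group / n_Cu,   total = holo / occupancy,
    apo = total − holo.

Nuclear MAC and ACE are not seen in the cytosolic chromatograms; their
totals are taken as invariant across the titration and partitioned into
apo/holo with the recalibrated Hill fits.  CTR expression is driven by
apo-MAC, so [CTR] is proportional to [aMAC].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import COMPONENTS, ReactionNetwork, cu_weight_vector
from .wegner import HillFit, apo_fraction

__all__ = [
    "ProteinEstimate",
    "ConditionProfile",
    "AVOGADRO",
    "protein_from_copper",
    "mac_ace_partition",
    "ctr_from_amac",
    "atoms_per_cell",
    "assemble_condition_table",
    "condition_table_frame",
]

AVOGADRO = 6.02214076e23  # mol⁻¹

#: Default ratio [CTR]/[aMAC], fixed by the reference-condition anchor
#: 0.29 μM / 0.37 μM.
CTR_PER_AMAC = 0.79

CONDITION_ORDER = ("MBCS", "M0", "M10", "M50", "M100", "M175", "M250")


@dataclass(frozen=True)
class ProteinEstimate:
    total: float  # μM
    holo: float  # μM

    def __post_init__(self) -> None:
        if self.holo < 0 or self.total < 0:
            raise ValueError("concentrations must be >= 0")
        if self.holo > self.total * (1 + 1e-12):
            raise ValueError("holo cannot exceed total")

    @property
    def apo(self) -> float:
        return self.total - self.holo


@dataclass(frozen=True)
class ConditionProfile:
    """One titration condition's boundary input and steady-state estimate."""

    label: str
    copper: float  # effective nutrient COPPER, μM
    cu_by_group: dict[str, float]  # μM Cu in groups CUP, OTH, CU
    occupancy: float  # fractional Cu occupancy of CUP/OTH proteins
    concentrations: dict[str, float]  # all 10 components, μM
    total_cell_cu: float = field(default=float("nan"))  # μM Cu equivalents

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        missing = set(COMPONENTS) - set(self.concentrations)
        if missing:
            raise ValueError(f"profile missing components: {sorted(missing)}")
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")


def protein_from_copper(
    cu_conc: float, cu_per_protein: int, occupancy: float
) -> ProteinEstimate:
    """Protein totals from group copper, Cu stoichiometry and occupancy."""
    if cu_conc < 0:
        raise ValueError("group copper must be >= 0")
    if cu_per_protein < 1:
        raise ValueError("cu_per_protein must be >= 1")
    if not 0.0 < occupancy <= 1.0:
        raise ValueError("occupancy must lie in (0, 1]")
    holo = cu_conc / cu_per_protein
    total = holo / occupancy
    return ProteinEstimate(total=total, holo=holo)


def mac_ace_partition(cu_um: float, total: float, fit: HillFit) -> ProteinEstimate:
    """Partition an invariant protein total into apo/holo at a given CU.

    ``fit`` must be on the recalibrated (labile-pool) scale; ``cu_um``
    is the labile-pool concentration in μM.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    apo = total * apo_fraction(cu_um * 1e-6, fit)
    return ProteinEstimate(total=total, holo=total - apo)


def ctr_from_amac(amac: float, ratio: float = CTR_PER_AMAC) -> float:
    """[CTR] proportional to [aMAC] (aMAC drives CTR expression)."""
    if amac < 0:
        raise ValueError("aMAC must be >= 0")
    return ratio * amac


def atoms_per_cell(conc_molar: float, cell_volume_l: float = 42e-15) -> float:
    """Number of solute molecules per cell at a given molar concentration."""
    if conc_molar < 0:
        raise ValueError("concentration must be >= 0")
    if not cell_volume_l > 0:
        raise ValueError("cell volume must be > 0")
    return conc_molar * cell_volume_l * AVOGADRO


def assemble_condition_table(
    raw: pd.DataFrame,
    mac_fit: HillFit,
    ace_fit: HillFit,
    mac_total: float,
    ace_total: float,
    network: ReactionNetwork,
    default_occupancy: float = 0.30,
    ctr_ratio: float = CTR_PER_AMAC,
) -> list[ConditionProfile]:
    """Build full component concentrations for every titration condition.

    ``raw`` must have columns ``condition``, ``COPPER_uM``, ``Cu_CUP_uM``,
    ``Cu_OTH_uM``, ``Cu_CU_uM`` and optionally ``occupancy``; a row for
    the reference condition M10 is required since it anchors rate-law
    normalizations.  ``mac_fit``/``ace_fit`` are Hill fits on the
    recalibrated labile-pool scale; ``mac_total``/``ace_total`` are the
    condition-invariant totals of the two transcription factors (μM).
    """
    raw = raw.set_index("condition") if "condition" in raw.columns else raw
    if "M10" not in raw.index:
        raise ValueError("condition table must contain the reference condition M10")

    weights = cu_weight_vector(network)
    cup_stoich = network.component("CUP").cu_stoichiometry
    oth_stoich = network.component("OTH").cu_stoichiometry

    profiles = []
    labels = [c for c in CONDITION_ORDER if c in raw.index]
    labels += [c for c in raw.index if c not in labels]
    for label in labels:
        row = raw.loc[label]
        occ = float(row.get("occupancy", np.nan))
        if np.isnan(occ):
            occ = default_occupancy
        cu = float(row["Cu_CU_uM"])
        cup = protein_from_copper(float(row["Cu_CUP_uM"]), cup_stoich, occ)
        oth = protein_from_copper(float(row["Cu_OTH_uM"]), oth_stoich, occ)
        mac = mac_ace_partition(cu, mac_total, mac_fit)
        ace = mac_ace_partition(cu, ace_total, ace_fit)
        conc = {
            "aMAC": mac.apo, "MAC": mac.holo,
            "aACE": ace.apo, "ACE": ace.holo,
            "aCUP": cup.apo, "CUP": cup.holo,
            "aOTH": oth.apo, "OTH": oth.holo,
            "CTR": ctr_from_amac(mac.apo, ctr_ratio),
            "CU": cu,
        }
        total_cu = float(sum(weights[name] * c for name, c in conc.items()))
        profiles.append(ConditionProfile(
            label=label,
            copper=float(row["COPPER_uM"]),
            cu_by_group={
                "CUP": float(row["Cu_CUP_uM"]),
                "OTH": float(row["Cu_OTH_uM"]),
                "CU": cu,
            },
            occupancy=occ,
            concentrations=conc,
            total_cell_cu=total_cu,
        ))
    return profiles


def condition_table_frame(profiles: list[ConditionProfile]) -> pd.DataFrame:
    """Tabular view: one row per condition, one column per component."""
    rows = {}
    for p in profiles:
        row = dict(p.concentrations)
        row["COPPER"] = p.copper
        row["total_cell_cu"] = p.total_cell_cu
        row["occupancy"] = p.occupancy
        rows[p.label] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "condition"
    return frame
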