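"""End-to-end calibration: titration table in, dynamical system out.

Chains the stages: condition estimation → null-space/basic-pathway
analysis → steady-state rate solving → apparent rate constants →
invariance classification → consolidation into a dynamical-system
parameter set.  The result bundles every intermediate product so each
stage can be inspected or exported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibration import (
    ParameterSet,
    RateConstantTable,
    apparent_constant_table,
    classify_invariance,
    consolidate_constants,
)
from .conditions import ConditionProfile
from .dynamics import DynamicalSystem
from .network import (
    ReactionNetwork,
    ReferenceState,
    build_canonical_network,
    stoichiometric_matrix,
)
from .pathways import (
    PathwayBasis,
    RateAssignment,
    calibrate_cuin1,
    independent_rate_assignment,
    nonnegative_pathway_basis,
    null_basis,
    solve_steady_state_rates,
    verify_flow_balance,
)
from .templates import MTitrationTemplate, default_template

__all__ = ["CalibrationResult", "run_calibration", "default_system"]


@dataclass
class CalibrationResult:
    network: ReactionNetwork
    S: pd.DataFrame
    W: PathwayBasis
    profiles: list[ConditionProfile]
    ref: ReferenceState
    k_cuin1: float
    assignments: list[RateAssignment]
    constant_table: RateConstantTable
    params: ParameterSet
    balance_report: list[dict]

    def system(self, copper: float) -> DynamicalSystem:
        return DynamicalSystem(
            network=self.network, params=self.params, ref=self.ref, copper=copper
        )

    def profile(self, label: str) -> ConditionProfile:
        return next(p for p in self.profiles if p.label == label)


def run_calibration(
    template: MTitrationTemplate | None = None,
    network: ReactionNetwork | None = None,
    seed: int = 0,
) -> CalibrationResult:
    """Run the full steady-state calibration for one titration template."""
    template = template or default_template()
    network = network or build_canonical_network()
    S = stoichiometric_matrix(network)
    W = nonnegative_pathway_basis(null_basis(S))

    profiles = template.profiles(network)
    ref = template.reference_state(network)
    mbcs = next(p for p in profiles if p.label == "MBCS")
    k1, cuin1_rates = calibrate_cuin1(mbcs, ref, network, profiles)

    assignments = []
    balance = []
    for p in profiles:
        partial = independent_rate_assignment(
            p, ref, cuin1_rates[p.label], network,
            demetallation_multiplier=template.demetallation_multiplier,
        )
        a = solve_steady_state_rates(W, partial, S)
        assignments.append(a)
        balance.append(verify_flow_balance(a, p, ref.alpha_cell))

    ktab = apparent_constant_table(assignments, profiles, ref, network)
    table = classify_invariance(ktab)
    params = consolidate_constants(table, profiles, seed=seed)
    table.consolidated = pd.Series(params.scalar_k)
    return CalibrationResult(
        network=network, S=S, W=W, profiles=profiles, ref=ref, k_cuin1=k1,
        assignments=assignments, constant_table=table, params=params,
        balance_report=balance,
    )


def default_system(copper: float = 14.0, seed: int = 0) -> DynamicalSystem:
    """Dynamical system calibrated from the default titration template."""
    return run_calibration(seed=seed).system(copper)
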