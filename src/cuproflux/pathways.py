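"""Null-space analysis of the stoichiometric matrix and steady-state rates.

At steady state S·R = 0, so the 25 reaction rates live in the
15-dimensional null space of the 10 × 25 stoichiometric matrix.  The
null space is first spanned by an algebraic basis G (exact, via rational
row reduction) and then re-expressed as a *basic pathway* basis W whose
entries are all nonnegative: each column of W is a physically meaningful
steady-state flow through a subset of reactions (nutrient in, growth
dilution out).  Basic pathways are found as vertices of sections of the
flux cone {v ≥ 0 : S v = 0} by minimum-total-flux linear programs, one
per reaction, keeping a linearly independent spanning subset.

Rates are then solved condition by condition: 15 reactions (the ten
dilutions, the four demetallations and the low-affinity import CUIN2)
are assigned independently, the pathway coefficients C_BP follow from
R = W·C_BP restricted to the independent rows, and the remaining ten
rates are read off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy
from scipy.optimize import linprog

from .conditions import ConditionProfile
from .network import ReactionNetwork, ReferenceState, evaluate_rate

__all__ = [
    "NullBasis",
    "PathwayBasis",
    "RateAssignment",
    "INDEPENDENT_REACTIONS",
    "null_basis",
    "nonnegative_pathway_basis",
    "independent_rate_assignment",
    "calibrate_cuin1",
    "solve_steady_state_rates",
    "verify_flow_balance",
]

#: Reactions whose steady-state rates are assigned independently.
INDEPENDENT_REACTIONS = (
    "DAMAC", "DMAC", "DAACE", "DACE", "DACUP",
    "DCUP", "DAOTH", "DOTH", "DCTR", "DCU",
    "MMACR", "MACER", "MCUPR", "MOTHR",
    "CUIN2",
)

#: demetallation -> dilution of the corresponding holo form
DEMETALLATION_PAIRS = {
    "MMACR": "DMAC", "MACER": "DACE", "MCUPR": "DCUP", "MOTHR": "DOTH",
}


@dataclass(frozen=True)
class NullBasis:
    """Columns span null(S); rows are labelled by reaction."""

    matrix: pd.DataFrame  # reactions × basis vectors

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PathwayBasis:
    """Nonnegative null-space basis; each column is a basic pathway."""

    matrix: pd.DataFrame  # reactions × pathways, all entries >= 0

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def pathway_labels(self) -> list[str]:
        """Describe each pathway by its participating reactions."""
        labels = []
        for col in self.matrix.columns:
            v = self.matrix[col]
            active = v[v > 1e-9 * v.max()].index.tolist()
            labels.append("+".join(active))
        return labels


@dataclass
class RateAssignment:
    """Per-condition steady-state rates and pathway coefficients."""

    condition: str
    rates: pd.Series  # μM/min, indexed by reaction
    independent: pd.Series  # bool, indexed by reaction
    c_bp: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def null_basis(S: pd.DataFrame) -> NullBasis:
    """Exact rational null-space basis of S (columns of G)."""
    M = sympy.Matrix(S.to_numpy())
    vecs = M.nullspace()
    G = np.column_stack([np.array(v, dtype=float).ravel() for v in vecs])
    return NullBasis(pd.DataFrame(G, index=S.columns,
                                  columns=[f"g{i+1}" for i in range(G.shape[1])]))


def _flux_cone_vertex(G: np.ndarray, r: int) -> np.ndarray | None:
    """Min-total-flux steady-state flow carrying unit flux on reaction r.

    Parameterizes v = G·x and solves the LP

        min Σ v  s.t.  v = G·x ≥ 0,  v_r = 1.

    The optimum is a vertex of a section of the flux cone, i.e. a basic
    pathway through reaction r (support-minimal up to degeneracy).
    Returns None if reaction r can carry no steady-state flux.
    """
    n_rxn, dim = G.shape
    c = G.sum(axis=0)
    res = linprog(
        c,
        A_ub=-G,
        b_ub=np.zeros(n_rxn),
        A_eq=G[r:r + 1],
        b_eq=[1.0],
        bounds=[(None, None)] * dim,
        method="highs",
    )
    if not res.success:
        return None
    v = G @ res.x
    v[np.abs(v) < 1e-10] = 0.0
    if (v < 0).any():
        return None
    return v


def nonnegative_pathway_basis(G: NullBasis, max_extra_passes: int = 50) -> PathwayBasis:
    """Transform an algebraic null basis into a basic-pathway basis W.

    Collects vertex flows (one LP per reaction), keeping those that
    increase the rank, until the full null-space dimension is reached.
    Columns are normalized so the largest entry is 1.  Raises if no
    nonnegative spanning set is found — negative entries are never
    returned silently.
    """
    Gm = G.matrix.to_numpy(dtype=float)
    n_rxn, dim = Gm.shape
    columns: list[np.ndarray] = []

    def try_add(v: np.ndarray | None) -> None:
        if v is None or v.max() <= 0:
            return
        trial = np.column_stack(columns + [v]) if columns else v[:, None]
        if np.linalg.matrix_rank(trial, tol=1e-9) > len(columns):
            columns.append(v / v.max())

    for r in range(n_rxn):
        if len(columns) == dim:
            break
        try_add(_flux_cone_vertex(Gm, r))

    # Degenerate LPs can revisit the same vertex; perturbed objectives
    # expose the remaining extreme rays.
    rng = np.random.default_rng(0)
    passes = 0
    while len(columns) < dim and passes < max_extra_passes:
        passes += 1
        w = 1.0 + rng.uniform(0, 1, size=n_rxn)
        for r in range(n_rxn):
            if len(columns) == dim:
                break
            res = linprog(
                w @ Gm, A_ub=-Gm, b_ub=np.zeros(n_rxn),
                A_eq=Gm[r:r + 1], b_eq=[1.0],
                bounds=[(None, None)] * dim, method="highs",
            )
            if res.success:
                v = Gm @ res.x
                v[np.abs(v) < 1e-10] = 0.0
                if (v >= 0).all():
                    try_add(v)
    if len(columns) < dim:
        raise RuntimeError(
            f"found only {len(columns)} of {dim} independent nonnegative flows"
        )
    W = np.column_stack(columns)
    if (W < 0).any():  # pragma: no cover - guarded above
        raise RuntimeError("pathway basis has negative entries")
    return PathwayBasis(pd.DataFrame(
        W, index=G.matrix.index, columns=[f"bp{i+1}" for i in range(dim)]))


def calibrate_cuin1(
    mbcs_profile: ConditionProfile,
    ref: ReferenceState,
    network: ReactionNetwork,
    profiles: list[ConditionProfile] | None = None,
    alpha: float | None = None,
) -> tuple[float, dict[str, float]]:
    """Rate constant of the high-affinity importer from the MBCS anchor.

    Under Cu-deficient (MBCS) growth all influx is assumed to pass
    through CUIN1 at α × total cellular Cu.  Inverting the
    Michaelis–Menten rate law (Km from the network's CUIN1 reaction) at
    the MBCS state yields k_CUIN1; per-condition CUIN1 rates follow from
    the same law at each condition's COPPER and CTR.
    """
    alpha = ref.alpha_cell if alpha is None else alpha
    if mbcs_profile.copper <= 0:
        raise ZeroDivisionError(
            "effective COPPER under MBCS must be positive (configure a trace value)"
        )
    rxn = network.reaction("CUIN1")
    influx = alpha * mbcs_profile.total_cell_cu
    factor = evaluate_rate(
        rxn, mbcs_profile.concentrations, mbcs_profile.copper, ref, k=1.0
    )
    k1 = influx / factor

    rates: dict[str, float] = {}
    for p in profiles if profiles is not None else [mbcs_profile]:
        rates[p.label] = evaluate_rate(rxn, p.concentrations, p.copper, ref, k=k1)
    return k1, rates


def independent_rate_assignment(
    profile: ConditionProfile,
    ref: ReferenceState,
    cuin1_rate: float,
    network: ReactionNetwork,
    alpha: float | None = None,
    demetallation_multiplier: float = 100.0,
) -> RateAssignment:
    """Assign the 15 independent steady-state rates for one condition.

    Dilution rates are α × concentration; each demetallation runs
    ``demetallation_multiplier`` times faster than the dilution of its
    holo form; CUIN2 carries whatever influx (α × total Cu) the
    high-affinity importer does not, floored at zero.
    """
    alpha = ref.alpha_cell if alpha is None else alpha
    rates = pd.Series(np.nan, index=list(network.reaction_names))
    for rxn in network.reactions:
        if rxn.name.startswith("D"):
            (species,) = rxn.substrates
            rates[rxn.name] = alpha * profile.concentrations[species]
    for demet, dil in DEMETALLATION_PAIRS.items():
        rates[demet] = demetallation_multiplier * rates[dil]
    notes: list[str] = []
    cuin2 = alpha * profile.total_cell_cu - cuin1_rate
    if cuin2 < -1e-8:
        warnings.warn(
            f"{profile.label}: CUIN1 exceeds total influx by {-cuin2:.3g} μM/min; "
            "import accounting inconsistent, CUIN2 floored at 0",
            stacklevel=2,
        )
        notes.append(f"CUIN2 floored (deficit {-cuin2:.3g})")
    rates["CUIN2"] = max(cuin2, 0.0)
    independent = pd.Series(
        [name in INDEPENDENT_REACTIONS for name in network.reaction_names],
        index=list(network.reaction_names),
    )
    return RateAssignment(profile.label, rates, independent, notes=notes)


def solve_steady_state_rates(
    W: PathwayBasis,
    partial: RateAssignment,
    S: pd.DataFrame,
    negativity_tolerance: float = 1e-8,
) -> RateAssignment:
    """Complete a partial rate assignment through the pathway basis.

    Solves W[independent rows] · C_BP = R[independent] for the 15
    pathway coefficients and reads the ten dependent rates off
    R = W·C_BP.  Dependent rates below −``negativity_tolerance`` raise;
    tiny negative values are clipped to zero with a note.
    """
    ind = [name for name in partial.rates.index if partial.independent[name]]
    dep = [name for name in partial.rates.index if not partial.independent[name]]
    W_ind = W.matrix.loc[ind].to_numpy()
    if W_ind.shape[0] != W_ind.shape[1] or np.linalg.matrix_rank(W_ind, tol=1e-9) < W_ind.shape[1]:
        raise np.linalg.LinAlgError(
            "independent rows of W are singular; chosen independents do not "
            "parameterize the null space"
        )
    c_bp = np.linalg.solve(W_ind, partial.rates[ind].to_numpy())
    R = pd.Series(W.matrix.to_numpy() @ c_bp, index=W.matrix.index)
    R[ind] = partial.rates[ind]  # exact by construction; avoid roundoff drift

    notes = list(partial.notes)
    bad = R[dep][R[dep] < -negativity_tolerance]
    if len(bad):
        raise ValueError(
            f"{partial.condition}: dependent rates infeasible (negative): "
            f"{bad.to_dict()}"
        )
    clipped = R[dep][(R[dep] < 0)]
    for name in clipped.index:
        notes.append(f"{name} clipped to 0 (was {R[name]:.2e})")
        R[name] = 0.0

    resid = np.abs(S.to_numpy() @ R.to_numpy()).max()
    scale = max(R.abs().max(), 1e-30)
    if resid > 1e-8 * scale:
        raise ValueError(f"S·R residual {resid:.3g} exceeds tolerance")
    return RateAssignment(partial.condition, R, partial.independent, c_bp, notes)


def verify_flow_balance(
    assignment: RateAssignment,
    profile: ConditionProfile,
    alpha: float,
    rel_tol: float = 1e-8,
) -> dict:
    """Check copper mass balance: total import equals growth dilution."""
    influx = assignment.rates["CUIN1"] + assignment.rates["CUIN2"]
    expected = alpha * profile.total_cell_cu
    residual = influx - expected
    ok = abs(residual) <= rel_tol * max(abs(expected), 1e-30)
    return {
        "condition": assignment.condition,
        "influx": float(influx),
        "alpha_times_total_cu": float(expected),
        "residual": float(residual),
        "balanced": bool(ok),
    }
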