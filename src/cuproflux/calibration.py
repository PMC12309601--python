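"""Back-calculation of rate constants and logistic regulation fits.

Given per-condition steady-state rates and concentrations, the apparent
rate constant of each reaction is the rate divided by the product of its
normalized rate-law factors.  True rate constants should be invariant
across the nutrient titration; reactions whose apparent constants climb
monotonically with supplementation are taken to be regulated at the
expression level.  That regulation is represented by a soft-Heaviside
(logistic) augmentation

    k_apparent(Sen) = k_invariant / (1 + exp(n (Sen_sp − Sen))),

where Sen is the sensed concentration (labile CU for BACUP, MCUPF and
MOTHF; nutrient COPPER for CUIN2), Sen_sp the setpoint at which the
apparent constant is half-maximal, and n > 0 a sensitivity factor
(feedforward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .conditions import CONDITION_ORDER, ConditionProfile
from .network import ReactionNetwork, ReferenceState, rate_law_factor
from .pathways import RateAssignment

__all__ = [
    "LogisticParams",
    "RateConstantTable",
    "ParameterSet",
    "REGULATED_REACTIONS",
    "apparent_rate_constant",
    "apparent_constant_table",
    "classify_invariance",
    "logistic_apparent_k",
    "fit_logistic",
    "consolidate_constants",
]

#: Reactions carrying the logistic augmentation and their sensed species.
REGULATED_REACTIONS = {"BACUP": "CU", "MCUPF": "CU", "MOTHF": "CU", "CUIN2": "COPPER"}


@dataclass(frozen=True)
class LogisticParams:
    k_invariant: float  # maximal rate constant
    sen_sp: float  # setpoint concentration, μM
    n_sens: float  # sensitivity, μM⁻¹ (positive: feedforward)
    sensed_species: str  # "CU" or "COPPER"

    def __post_init__(self) -> None:
        if not self.k_invariant > 0:
            raise ValueError("k_invariant must be > 0")
        if not self.n_sens > 0:
            raise ValueError("n_sens must be > 0 (feedforward)")


@dataclass
class RateConstantTable:
    """Apparent rate constants by condition plus invariance classes."""

    constants: pd.DataFrame  # reactions × conditions
    invariance: pd.Series  # "invariant" | "trending" | "unclassified"
    consolidated: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def trending(self) -> list[str]:
        return sorted(self.invariance.index[self.invariance == "trending"])

    @property
    def invariant(self) -> list[str]:
        return sorted(self.invariance.index[self.invariance == "invariant"])


@dataclass
class ParameterSet:
    """Complete dynamical-system parameterization.

    ``scalar_k`` holds one consolidated constant per unregulated
    reaction; ``logistic`` a LogisticParams triple per regulated one.
    """

    scalar_k: dict[str, float]
    logistic: dict[str, LogisticParams]

    def validate(self, network: ReactionNetwork) -> None:
        missing = [
            r.name
            for r in network.reactions
            if r.name not in self.scalar_k and r.name not in self.logistic
        ]
        if missing:
            raise ValueError(f"incomplete parameterization, missing: {missing}")

    def frozen(self) -> "ParameterSet":
        """Regulation ablated: each logistic replaced by its plateau."""
        scalar = dict(self.scalar_k)
        for name, lp in self.logistic.items():
            scalar[name] = lp.k_invariant
        return ParameterSet(scalar_k=scalar, logistic={})


def apparent_rate_constant(
    reaction_name: str,
    steady_rate: float,
    profile: ConditionProfile,
    ref: ReferenceState,
    network: ReactionNetwork,
) -> float:
    """k = rate / (normalized rate-law factors), logistic factor excluded."""
    rxn = network.reaction(reaction_name)
    factor = rate_law_factor(rxn, profile.concentrations, profile.copper, ref)
    if factor == 0.0:
        raise ZeroDivisionError(
            f"{reaction_name} at {profile.label}: rate-law factor is zero "
            "(vanishing substrate or catalyst); apparent k undefined"
        )
    return steady_rate / factor


def apparent_constant_table(
    assignments: list[RateAssignment],
    profiles: list[ConditionProfile],
    ref: ReferenceState,
    network: ReactionNetwork,
) -> pd.DataFrame:
    """Apparent rate constants for every reaction × condition."""
    by_label = {p.label: p for p in profiles}
    cols = {}
    for a in assignments:
        profile = by_label[a.condition]
        col = {}
        for name in network.reaction_names:
            try:
                col[name] = apparent_rate_constant(
                    name, float(a.rates[name]), profile, ref, network
                )
            except ZeroDivisionError:
                col[name] = np.nan
        cols[a.condition] = col
    frame = pd.DataFrame(cols)
    ordered = [c for c in CONDITION_ORDER if c in frame.columns]
    return frame[ordered + [c for c in frame.columns if c not in ordered]]


def classify_invariance(
    constants: pd.DataFrame,
    rel_spread_threshold: float = 0.5,
    min_defined: int = 5,
) -> RateConstantTable:
    """Label each reaction invariant or trending across the titration.

    A reaction trends iff its apparent constants are monotonically
    nondecreasing across the ordered conditions, strictly larger at the
    end than at the start, and spread by more than
    ``rel_spread_threshold`` relative (max/min − 1, infinite when the
    smallest value is zero).  Everything else with enough defined values
    is invariant.
    """
    classes = {}
    for name, row in constants.iterrows():
        vals = row.to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) < min_defined:
            classes[name] = "unclassified"
            continue
        diffs = np.diff(defined)
        monotone = (diffs >= -1e-9 * np.abs(defined[:-1]).max()).all()
        increasing = defined[-1] > defined[0]
        vmin, vmax = defined.min(), defined.max()
        spread = math.inf if vmin <= 0 else vmax / vmin - 1.0
        classes[name] = (
            "trending"
            if monotone and increasing and spread > rel_spread_threshold
            else "invariant"
        )
    return RateConstantTable(constants, pd.Series(classes))


def logistic_apparent_k(params: LogisticParams, sen: float) -> float:
    """Soft-Heaviside apparent rate constant at sensed concentration ``sen``."""
    if sen < 0:
        raise ValueError("sensed concentration must be >= 0")
    z = params.n_sens * (params.sen_sp - sen)
    z = min(max(z, -700.0), 700.0)  # overflow guard; exact within float
    return params.k_invariant / (1.0 + math.exp(z))


def fit_logistic(
    k_points: np.ndarray,
    sen_points: np.ndarray,
    sensed_species: str,
    k_invariant_bounds: tuple[float, float] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> LogisticParams:
    """Least-squares logistic fit of apparent constants vs sensed species.

    Multi-start bounded least squares (deterministic seed).  When
    ``k_invariant_bounds`` is not given, the plateau is constrained to
    [0.5×, 5×] the largest apparent constant — the trending data rarely
    reach their plateau, so an unconstrained fit is ill-posed.
    """
    k = np.asarray(k_points, dtype=float)
    sen = np.asarray(sen_points, dtype=float)
    ok = ~np.isnan(k) & ~np.isnan(sen)
    k, sen = k[ok], sen[ok]
    if len(k) < 4:
        raise ValueError(f"need at least 4 (k, Sen) pairs, got {len(k)}")
    kmax = k.max()
    if k_invariant_bounds is None:
        k_invariant_bounds = (0.5 * kmax, 5.0 * kmax)
    lo = np.array([k_invariant_bounds[0], sen.min() * 1e-2, 1e-6])
    hi = np.array([k_invariant_bounds[1], sen.max() * 1e2, 1e4 / max(sen.max(), 1e-12)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        kinv, sp, n = theta
        z = np.clip(n * (sp - sen), -700, 700)
        return kinv / (1.0 + np.exp(z)) - k

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = np.array([kmax * 1.5, np.median(sen), 2.0 / max(np.ptp(sen), 1e-9)])
        else:
            u = rng.uniform(size=3)
            x0 = lo * (hi / lo) ** u  # log-uniform in the box
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-10 * max(best.cost, 1e-300):
            best = res
    if best is None or not best.success:
        raise RuntimeError("logistic fit failed to converge after restarts")
    kinv, sp, n = best.x
    return LogisticParams(float(kinv), float(sp), float(n), sensed_species)


def consolidate_constants(
    table: RateConstantTable,
    profiles: list[ConditionProfile],
    seed: int = 0,
) -> ParameterSet:
    """Average invariant constants; fit logistics for the regulated four.

    The sensed abscissa per condition is the labile-pool CU (from the
    profile) or nutrient COPPER, per ``REGULATED_REACTIONS``.  Reactions
    classified trending but not in the regulated set are treated as
    invariant with a warning note (the canonical model regulates exactly
    four).
    """
    by_label = {p.label: p for p in profiles}
    sen_values = {
        "CU": np.array([by_label[c].concentrations["CU"] for c in table.constants.columns]),
        "COPPER": np.array([by_label[c].copper for c in table.constants.columns]),
    }
    scalar_k: dict[str, float] = {}
    logistic: dict[str, LogisticParams] = {}
    for name, row in table.constants.iterrows():
        if name in REGULATED_REACTIONS:
            species = REGULATED_REACTIONS[name]
            logistic[name] = fit_logistic(
                row.to_numpy(dtype=float), sen_values[species], species, seed=seed
            )
        else:
            vals = row.to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                raise ValueError(f"no defined apparent constants for {name}")
            scalar_k[name] = float(vals.mean())
    return ParameterSet(scalar_k=scalar_k, logistic=logistic)
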