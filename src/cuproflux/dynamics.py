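"""The assembled dynamical system and its in-silico experiments.

dC/dt = S·R(C): ten ODEs driven by the 25 rate laws, with consolidated
rate constants for the unregulated reactions and logistic (soft
Heaviside) apparent constants for the four regulated ones.  Nutrient
COPPER is a fixed boundary parameter of each system instance.

Experiments mirror how such a homeostat is probed: *annealing* (relax
each titration condition's estimated state to the model's own attractor,
absorbing small calibration inconsistencies), instantaneous component
perturbations, nutrient steps, reaction knockouts (rate constant set to
zero) and steady-state nutrient sweeps with a homeostatic-slope readout
(nM change in labile CU per μM nutrient COPPER).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import approx_fprime

from .calibration import ParameterSet, logistic_apparent_k
from .network import (
    ReactionNetwork,
    ReferenceState,
    evaluate_rate,
    stoichiometric_matrix,
)

__all__ = [
    "DynamicalSystem",
    "Trajectory",
    "SteadyStateResult",
    "assemble_derivatives",
    "integrate",
    "anneal",
    "perturb_component",
    "step_nutrient",
    "knockout",
    "sweep_nutrient",
    "homeostatic_slope",
    "recovery_time",
]

#: Convergence criterion on max |dC/dt| (μM/min).
STEADY_STATE_RESIDUAL = 1e-9

ANNEAL_TIME = 20_000.0  # min


@dataclass(frozen=True)
class DynamicalSystem:
    network: ReactionNetwork
    params: ParameterSet
    ref: ReferenceState
    copper: float  # μM, fixed boundary condition
    knockout_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params.validate(self.network)
        if self.copper < 0:
            raise ValueError("COPPER must be >= 0")
        for name, m in self.knockout_multipliers.items():
            if name not in self.network.reaction_names:
                raise KeyError(f"unknown reaction {name!r}")
            if m < 0:
                raise ValueError("knockout multiplier must be >= 0")

    def with_copper(self, copper: float) -> "DynamicalSystem":
        return dataclasses.replace(self, copper=copper)

    def rates(self, state: dict[str, float]) -> pd.Series:
        """All 25 reaction rates (μM/min) at the given state."""
        out = {}
        for rxn in self.network.reactions:
            lp = self.params.logistic.get(rxn.name)
            if lp is not None:
                sen = self.copper if lp.sensed_species == "COPPER" else state["CU"]
                k = logistic_apparent_k(lp, sen)
            else:
                k = self.params.scalar_k[rxn.name]
            k *= self.knockout_multipliers.get(rxn.name, 1.0)
            out[rxn.name] = evaluate_rate(
                rxn, state, self.copper, self.ref, k=k, logistic_factor=1.0
            )
        return pd.Series(out)


@dataclass
class Trajectory:
    times: np.ndarray  # min
    states: pd.DataFrame  # times × components, μM
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def final_state(self) -> dict[str, float]:
        return self.states.iloc[-1].to_dict()


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]
    residual: float  # max |dC/dt|, μM/min
    converged: bool
    time: float  # integration time used, min


def assemble_derivatives(system: DynamicalSystem):
    """Vectorized derivative function f(t, y) = S·R(y).

    Components follow the network's canonical order.  Concentrations are
    clamped at zero inside the rate evaluation, which keeps the
    integrator out of the (unphysical) negative orthant.
    """
    names = system.network.component_names
    S = stoichiometric_matrix(system.network).to_numpy(dtype=float)

    def f(t: float, y: np.ndarray) -> np.ndarray:
        state = {n: max(c, 0.0) for n, c in zip(names, y)}
        R = system.rates(state).to_numpy()
        return S @ R

    return f


def _state_vector(system: DynamicalSystem, state: dict[str, float]) -> np.ndarray:
    return np.array([state[n] for n in system.network.component_names])


def integrate(
    system: DynamicalSystem,
    y0: dict[str, float],
    t_span: tuple[float, float],
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Stiff-capable integration on a dense output grid."""
    f = assemble_derivatives(system)
    y = _state_vector(system, y0)
    if (y < 0).any():
        raise ValueError("initial state must be nonnegative")
    times = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(
        f, t_span, y, method="LSODA", t_eval=times, rtol=rtol, atol=atol
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"integration failed: {sol.message} (the demetallation multiplier "
            "bounds system stiffness; consider lowering it)"
        )
    states = pd.DataFrame(
        np.clip(sol.y.T, 0.0, None),
        index=sol.t,
        columns=list(system.network.component_names),
    )
    return Trajectory(times=sol.t, states=states)


def anneal(
    system: DynamicalSystem,
    y0: dict[str, float],
    t_max: float = ANNEAL_TIME,
) -> SteadyStateResult:
    """Relax an estimated state to the system's attracting steady state."""
    traj = integrate(system, y0, (0.0, t_max), n_points=50)
    final = traj.final_state
    f = assemble_derivatives(system)
    residual = float(np.abs(f(t_max, _state_vector(system, final))).max())
    return SteadyStateResult(
        concentrations=final,
        residual=residual,
        converged=residual < STEADY_STATE_RESIDUAL,
        time=t_max,
    )


def jacobian(system: DynamicalSystem, state: dict[str, float]) -> np.ndarray:
    """Numerical Jacobian of the derivative field at a state."""
    f = assemble_derivatives(system)
    y = _state_vector(system, state)
    eps = np.maximum(1e-8 * np.abs(y), 1e-10)
    return np.array(
        [approx_fprime(y, lambda v, i=i: f(0.0, v)[i], eps) for i in range(len(y))]
    )


def recovery_time(
    traj: Trajectory,
    baseline: dict[str, float],
    t_event: float,
    rel_tol: float = 0.01,
    sustain: float = 50.0,
) -> float:
    """First time after ``t_event`` at which every component stays within
    ``rel_tol`` of ``baseline`` for at least ``sustain`` minutes.

    Returns ``nan`` if the trajectory never settles within tolerance.
    """
    names = traj.states.columns
    base = np.array([baseline[n] for n in names])
    scale = np.maximum(np.abs(base), 1e-12)
    dev = np.abs(traj.states.to_numpy() - base) / scale
    within = (dev <= rel_tol).all(axis=1)
    times = traj.times
    for i in np.flatnonzero(within & (times >= t_event)):
        if times[-1] < times[i] + sustain - 1e-9:
            break  # trajectory too short to confirm the sustain window
        j = np.searchsorted(times, times[i] + sustain, side="right")
        if within[i:j].all():
            return float(times[i])
    return float("nan")


def perturb_component(
    system: DynamicalSystem,
    baseline: dict[str, float],
    component: str,
    factor: float,
    t_event: float = 100.0,
    t_end: float = 2000.0,
    n_points: int = 2000,
) -> tuple[Trajectory, dict]:
    """Instantaneously scale one component and follow the relaxation.

    The perturbation is a state discontinuity: integration runs to
    ``t_event``, the component is multiplied by ``factor`` and
    integration restarts.  Returns the stitched trajectory plus recovery
    metrics (time to return within 1% of baseline, sustained 50 min, and
    per-component recovery half-lives).
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be > 0")
    if component not in system.network.component_names:
        raise KeyError(component)
    pre = integrate(system, baseline, (0.0, t_event),
                    n_points=max(int(n_points * t_event / t_end), 16))
    bumped = dict(pre.final_state)
    bumped[component] = bumped[component] * factor
    post = integrate(system, bumped, (t_event, t_end), n_points=n_points)
    states = pd.concat([pre.states.iloc[:-1], post.states])
    traj = Trajectory(
        times=states.index.to_numpy(),
        states=states,
        events=[(t_event, f"{component} x{factor:g}")],
    )
    t_rec = recovery_time(traj, baseline, t_event)
    half_lives = {}
    for name in traj.states.columns:
        # time from each component's peak excursion back to half-peak;
        # components barely disturbed get 0
        dev = np.abs(post.states[name].to_numpy() - baseline[name])
        i_peak = int(np.argmax(dev))
        peak = dev[i_peak]
        if peak <= 1e-6 * max(abs(baseline[name]), 1e-12):
            half_lives[name] = 0.0
            continue
        idx = np.flatnonzero(dev[i_peak:] <= 0.5 * peak)
        half_lives[name] = (
            float(post.times[i_peak + idx[0]] - post.times[i_peak])
            if len(idx)
            else float("nan")
        )
    metrics = {
        "recovery_time": (t_rec - t_event) if np.isfinite(t_rec) else float("nan"),
        "half_lives": half_lives,
    }
    return traj, metrics


def step_nutrient(
    system: DynamicalSystem,
    baseline: dict[str, float],
    copper_from: float,
    copper_to: float,
    t_event: float = 100.0,
    t_end: float = 3000.0,
    n_points: int = 2000,
) -> Trajectory:
    """Abrupt change of nutrient COPPER at ``t_event``."""
    sys_from = system.with_copper(copper_from)
    sys_to = system.with_copper(copper_to)
    pre = integrate(sys_from, baseline, (0.0, t_event),
                    n_points=max(int(n_points * t_event / t_end), 16))
    post = integrate(sys_to, pre.final_state, (t_event, t_end), n_points=n_points)
    states = pd.concat([pre.states.iloc[:-1], post.states])
    return Trajectory(
        times=states.index.to_numpy(),
        states=states,
        events=[(t_event, f"COPPER {copper_from:g} -> {copper_to:g}")],
    )


def knockout(system: DynamicalSystem, reaction_name: str) -> DynamicalSystem:
    """A copy of the system with one reaction's rate constant zeroed."""
    if reaction_name not in system.network.reaction_names:
        raise KeyError(f"unknown reaction {reaction_name!r}")
    mult = dict(system.knockout_multipliers)
    mult[reaction_name] = 0.0
    return dataclasses.replace(system, knockout_multipliers=mult)


def sweep_nutrient(
    system: DynamicalSystem,
    copper_values: np.ndarray,
    baseline: dict[str, float],
    t_settle: float = ANNEAL_TIME,
) -> pd.DataFrame:
    """Steady-state concentrations at each nutrient COPPER value.

    Each point integrates the system at fixed COPPER for ``t_settle``
    minutes from the supplied baseline; non-converged rows are flagged.
    """
    rows = {}
    for copper in np.asarray(copper_values, dtype=float):
        res = anneal(system.with_copper(copper), baseline, t_max=t_settle)
        row = dict(res.concentrations)
        row["converged"] = res.converged
        rows[copper] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "COPPER"
    return table


def homeostatic_slope(
    sweep_table: pd.DataFrame,
    window: tuple[float, float] = (10.0, 50.0),
    species: str = "CU",
) -> float:
    """Least-squares slope of [species] vs COPPER in nM per μM.

    The flatter the slope, the more effective the homeostat; perfect
    regulation gives zero.
    """
    sel = sweep_table[
        (sweep_table.index >= window[0]) & (sweep_table.index <= window[1])
    ]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 sweep points in window {window}, got {len(sel)}")
    slope_um_per_um = np.polyfit(sel.index.to_numpy(), sel[species].to_numpy(), 1)[0]
    return float(slope_um_per_um * 1e3)
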