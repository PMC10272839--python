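"""Integration and steady-state solving for compiled reaction networks.

Uses scipy's LSODA (switching stiff/non-stiff) which copes with the fast
IKK/IkB binding reactions alongside slow synthesis. Trajectories are clipped
to zero from below; excursions are bounded by the absolute tolerance and
anything worse raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .compile import CompiledModel
from .model import ModelSpec, Stimulus, StimulusProfile, Trajectory

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8
STEADY_TOL = 1e-6
STEADY_HORIZON_H = 500.0
_EPS = 1e-9


class IntegrationError(RuntimeError):
    """Solver failed to produce a trajectory within tolerances."""


def _as_compiled(spec_or_model: ModelSpec | CompiledModel) -> CompiledModel:
    if isinstance(spec_or_model, CompiledModel):
        return spec_or_model
    return CompiledModel(spec_or_model)


def integrate(
    spec: ModelSpec | CompiledModel,
    initial_state: np.ndarray,
    stimuli: Mapping[str, Stimulus] | None = None,
    t_span: tuple[float, float] = (0.0, 8.0),
    t_eval: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    cell_id: int | None = None,
) -> Trajectory:
    """Integrate the network over ``t_span`` (hours) and return a Trajectory."""
    model = _as_compiled(spec)
    x0 = np.asarray(initial_state, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be >= 0")
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 161)
    sol = solve_ivp(
        lambda t, x: model.rhs(t, x, stimuli),
        t_span,
        x0,
        method="LSODA",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    states = sol.y.T
    worst = states.min(initial=0.0)
    if worst < -max(100 * atol, 1e-6):
        raise IntegrationError(
            f"negative excursion {worst:.3g} exceeds tolerance; model may be ill-posed"
        )
    return Trajectory(times=sol.t, states=np.clip(states, 0.0, None), spec=model.spec, cell_id=cell_id)


@dataclass(frozen=True)
class SteadyStateResult:
    state: np.ndarray
    converged: bool
    residual: float  # max_i |dx_i/dt| / (|x_i| + eps), 1/h
    t_elapsed: float


def _residual(model: CompiledModel, state: np.ndarray, stimuli) -> float:
    dx = model.rhs(0.0, state, stimuli)
    return float(np.max(np.abs(dx) / (np.abs(state) + _EPS)))


def run_to_steady_state(
    spec: ModelSpec | CompiledModel,
    initial_state: np.ndarray | None = None,
    basal_input: Mapping[str, Stimulus] | None = None,
    steady_tol: float = STEADY_TOL,
    horizon: float = STEADY_HORIZON_H,
    polish: bool = True,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SteadyStateResult:
    """Relax the network to steady state under constant basal input.

    Integrates in chunks until the relative derivative norm
    max |dx/dt|/(|x|+eps) falls below ``steady_tol`` (1/h) or the horizon is
    reached (flagged, not raised). When close, optionally polishes with a
    Newton root solve, accepted only if it lands non-negative and reduces
    the residual.
    """
    model = _as_compiled(spec)
    if basal_input is not None:
        for stim in basal_input.values():
            if not stim.is_constant:
                raise ValueError("steady-state phase requires constant basal input")
    x = model.spec.initial_state() if initial_state is None else np.asarray(initial_state, float)
    t_elapsed = 0.0
    chunk = 50.0
    res = _residual(model, x, basal_input)
    while res > steady_tol and t_elapsed < horizon:
        sol = solve_ivp(
            lambda t, y: model.rhs(t, y, basal_input),
            (0.0, chunk),
            x,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"steady-state integration failed: {sol.message}")
        x = np.clip(sol.y[:, -1], 0.0, None)
        t_elapsed += chunk
        new_res = _residual(model, x, basal_input)
        if polish and new_res < 1e3 * steady_tol:
            sol_r = root(lambda y: model.rhs(0.0, y, basal_input), x, method="hybr")
            if sol_r.success and np.all(sol_r.x >= -atol):
                cand = np.clip(sol_r.x, 0.0, None)
                cand_res = _residual(model, cand, basal_input)
                if cand_res < new_res and np.allclose(cand, x, rtol=0.05, atol=10 * atol):
                    x, new_res = cand, cand_res
        res = new_res
        chunk = min(chunk * 2, horizon - t_elapsed) or chunk
    return SteadyStateResult(state=x, converged=res <= steady_tol, residual=res, t_elapsed=t_elapsed)


def constant_input(name: str, level: float) -> dict[str, StimulusProfile]:
    return {name: StimulusProfile.constant(name, level)}
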