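"""Time-course simulation of an assembled rate model and attractor labeling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .model_build import RateModel
from .multieq import EquilibriumRecord

__all__ = ["Trajectory", "simulate", "classify_attractor", "FIGURE5_INITIALS"]

# the four printed initial conditions of the bistable example's sensitivity
# experiment, keyed (a)-(d); state order (C_1, C_2, C_3)
FIGURE5_INITIALS = {
    "a": (0.2, 0.728, 2.519),
    "b": (0.2, 0.728, 2.520),
    "c": (0.2, 0.723, 2.519),
    "d": (0.2, 0.729, 2.520),
}

NEGATIVE_CLIP = 1e-12


@dataclass
class Trajectory:
    times: np.ndarray           # strictly increasing, from 0 to t_end
    states: np.ndarray          # (len(times), n_states), non-negative
    attractor_id: Union[int, str] = "none"

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]


def simulate(
    model: RateModel,
    c0,
    t_end: float = 2000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 500,
) -> Trajectory:
    """Integrate dC/dt = R(C;P) on [0, t_end] with a stiff-capable solver.

    Uses LSODA with the analytic Jacobian.  Tiny negative undershoot below
    1e-12 is clipped to 0 in the reported states.
    """
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (model.n_states,):
        raise ValueError(f"initial state must have shape ({model.n_states},)")
    if np.any(c0 < 0):
        raise ValueError("initial state must be non-negative")
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, c: model.rhs(np.maximum(c, 0.0)),
        (0.0, t_end),
        c0,
        method="LSODA",
        jac=lambda t, c: model.jacobian(np.maximum(c, NEGATIVE_CLIP)),
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0:g}: "
            f"{sol.message}"
        )
    states = sol.y.T.copy()
    states[(states < 0) & (states > -NEGATIVE_CLIP)] = 0.0
    return Trajectory(times=sol.t, states=states)


def classify_attractor(
    trajectory: Trajectory,
    equilibria: Sequence[EquilibriumRecord],
    tol: float = 1e-4,
) -> Union[int, str]:
    """Index of the equilibrium the trajectory has settled on, or "none".

    The terminal state must be within ``tol`` (max-norm) of the equilibrium
    and stay there over the final 10% of the time grid.
    """
    if not equilibria:
        import warnings

        warnings.warn("empty equilibrium list: classifying as 'none'", stacklevel=2)
        return "none"
    tail_start = int(0.9 * len(trajectory.times))
    tail = trajectory.states[tail_start:]
    for idx, rec in enumerate(equilibria):
        if np.max(np.abs(tail - rec.c[None, :])) < tol:
            return idx
    return "none"


def trajectory_to_csv(model: RateModel, trajectory: Trajectory) -> str:
    header = ",".join(["time"] + [f"C_{name}" for name in model.states])
    lines = [header]
    for t, row in zip(trajectory.times, trajectory.states):
        lines.append(",".join([f"{t:.10g}"] + [f"{x:.10g}" for x in row]))
    return "\n".join(lines) + "\n"
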