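"""Assembly of the vector-form ODE model dC/dt = R(C;P) from a validated module.

Each reaction j contributes the stoichiometric column (beta_j - alpha_j),
where alpha_j / beta_j are the coordinates of the substrate / product in the
state basis (zero vectors for input / output nodes).  The right-hand side is
R(C;P) = sum_j (beta_j - alpha_j) v_j(C;P) and the Jacobian is assembled from
the exact analytic rate partials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import ConfigurationError, UnsupportedModuleError
from .ssi_graph import (
    KineticParams,
    SSIModule,
    classify_nodes,
    state_order,
)

__all__ = ["ParameterSet", "RateModel", "build_rate_model", "evaluate_rhs",
           "analytic_jacobian"]


@dataclass
class ParameterSet:
    """Numeric parameters of a model: per-reaction kinetic constants and the
    fixed concentration of every input node (input concentrations are
    parameters, never state variables)."""

    kinetics: dict[str, KineticParams] = field(default_factory=dict)
    inputs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for node, value in self.inputs.items():
            if not value > 0:
                raise ConfigurationError(
                    f"input concentration for {node!r} must be positive, got {value}"
                )


@dataclass(frozen=True)
class _CompiledReaction:
    index: int
    rid: str
    sub_idx: Optional[int]    # state index of the substrate, None if input
    inh_idx: Optional[int]    # state index of the (single) inhibitor, None if none
    input_conc: Optional[float]  # fixed substrate concentration for input substrates
    params: KineticParams
    reaction: object


class RateModel:
    """The assembled model: state ordering, stoichiometric columns and
    per-reaction rate evaluation.

    ``alpha`` and ``beta`` are (n_states x m) 0/1 matrices whose j-th columns
    are the substrate and product coordinates of reaction j.  Evaluation is
    vectorized over reactions; the scalar rate laws in :mod:`ssimod.kinetics`
    are the reference implementation and the two agree to machine precision
    (covered by tests).
    """

    def __init__(self, module: SSIModule, params: ParameterSet,
                 states: tuple[str, ...], alpha: np.ndarray, beta: np.ndarray,
                 compiled: tuple[_CompiledReaction, ...]):
        self.module = module
        self.params = params
        self.states = states
        self.alpha = alpha
        self.beta = beta
        self.stoich = beta - alpha          # columns (beta_j - alpha_j)
        self._compiled = compiled
        m = len(compiled)
        self._vmax = np.array([cr.params.v_max for cr in compiled])
        self._k = np.array([cr.params.k for cr in compiled])
        self._n = np.array([cr.params.n for cr in compiled])
        self._sub = np.array(
            [-1 if cr.sub_idx is None else cr.sub_idx for cr in compiled]
        )
        self._inh = np.array(
            [-1 if cr.inh_idx is None else cr.inh_idx for cr in compiled]
        )
        self._input_conc = np.array(
            [0.0 if cr.input_conc is None else cr.input_conc for cr in compiled]
        )
        kc = np.full(m, np.inf)
        ku = np.full(m, np.inf)
        for j, cr in enumerate(compiled):
            if cr.inh_idx is not None:
                inh = cr.reaction.inhibitors[0]
                kc[j] = cr.params.k_c[inh]
                ku[j] = cr.params.k_u[inh]
        self._kc, self._ku = kc, ku

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_reactions(self) -> int:
        return len(self._compiled)

    def _check_state(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        if c.shape != (self.n_states,):
            raise ValueError(
                f"state vector must have shape ({self.n_states},), got {c.shape}"
            )
        return c

    def _substrate_inhibitor_conc(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c_a = np.where(self._sub >= 0, c[self._sub], self._input_conc)
        c_i = np.where(self._inh >= 0, c[self._inh], 0.0)
        return c_a, c_i

    def reaction_rates(self, c) -> np.ndarray:
        """Vector of the m reaction rates v_j at state c."""
        c = self._check_state(c)
        c_a, c_i = self._substrate_inhibitor_conc(c)
        cn = c_a ** self._n
        den = self._k * (1.0 + c_i / self._kc) + cn * (1.0 + c_i / self._ku)
        return self._vmax * cn / den

    def rhs(self, c) -> np.ndarray:
        """R(C;P) = sum_j (beta_j - alpha_j) v_j(C;P)."""
        return self.stoich @ self.reaction_rates(c)

    def rate_gradients(self, c) -> np.ndarray:
        """(m x n) matrix G with G[j, i] = dv_j / dC_i."""
        c = self._check_state(c)
        c_a, c_i = self._substrate_inhibitor_conc(c)
        cn = c_a ** self._n
        e_c = 1.0 + c_i / self._kc
        den = self._k * e_c + cn * (1.0 + c_i / self._ku)
        with np.errstate(divide="ignore", invalid="ignore"):
            dva = self._vmax * self._n * c_a ** (self._n - 1.0) * self._k * e_c / den ** 2
        # C_A = 0 with n > 1 has derivative 0 (0**negative above gives inf)
        dva = np.where(c_a == 0.0,
                       np.where(self._n == 1.0, self._vmax / (self._k * e_c), 0.0),
                       dva)
        dvi = -self._vmax * cn * (self._k / self._kc + cn / self._ku) / den ** 2
        g = np.zeros((self.n_reactions, self.n_states))
        rows = np.arange(self.n_reactions)
        has_sub = self._sub >= 0
        np.add.at(g, (rows[has_sub], self._sub[has_sub]), dva[has_sub])
        has_inh = self._inh >= 0
        np.add.at(g, (rows[has_inh], self._inh[has_inh]), dvi[has_inh])
        return g

    def jacobian(self, c) -> np.ndarray:
        """Exact Jacobian dR/dC = S G, with S the stoichiometric matrix."""
        return self.stoich @ self.rate_gradients(c)


def build_rate_model(module: SSIModule, params: ParameterSet) -> RateModel:
    """Compile a validated module plus parameters into a :class:`RateModel`.

    Raises :class:`ConfigurationError` for missing parameters and
    :class:`UnsupportedModuleError` for reactions with several inhibitors or
    inhibitors that are input/output nodes (the rate laws cover neither).
    """
    roles = classify_nodes(module).roles
    states = state_order(module)
    index = {s: i for i, s in enumerate(states)}
    n, m = len(states), len(module.reactions)

    for node in module.nodes:
        if roles[node] == "input" and node not in params.inputs:
            raise ConfigurationError(
                f"input node {node!r} has no fixed concentration in the parameter set"
            )

    alpha = np.zeros((n, m))
    beta = np.zeros((n, m))
    compiled = []
    for j, r in enumerate(module.reactions):
        p = params.kinetics.get(r.id) or r.params
        if p is None:
            raise ConfigurationError(f"no kinetic parameters for reaction {r.id!r}")
        if len(r.inhibitors) > 1:
            raise UnsupportedModuleError(
                f"reaction {r.id!r} has more than one inhibitor"
            )
        inh_idx = None
        if r.inhibitors:
            inh = r.inhibitors[0]
            if roles[inh] != "state":
                raise UnsupportedModuleError(
                    f"inhibitor {inh!r} of reaction {r.id!r} is an "
                    f"{roles[inh]} node; only state-node inhibitors are modeled"
                )
            inh_idx = index[inh]
        sub_idx = input_conc = None
        if roles[r.substrate] == "state":
            alpha[index[r.substrate], j] = 1.0
            sub_idx = index[r.substrate]
        elif roles[r.substrate] == "input":
            input_conc = params.inputs[r.substrate]
        else:  # output-node substrate cannot occur: outputs have no outgoing edges
            raise ConfigurationError(
                f"reaction {r.id!r} consumes output node {r.substrate!r}"
            )
        if roles[r.product] == "state":
            beta[index[r.product], j] = 1.0
        if sub_idx is None and roles[r.product] != "state":
            raise ConfigurationError(
                f"reaction {r.id!r} touches no state node (alpha_j = beta_j = 0)"
            )
        compiled.append(
            _CompiledReaction(
                index=j, rid=r.id, sub_idx=sub_idx, inh_idx=inh_idx,
                input_conc=input_conc, params=p, reaction=r,
            )
        )
    return RateModel(module, params, states, alpha, beta, tuple(compiled))


def evaluate_rhs(model: RateModel, c) -> np.ndarray:
    """Functional form of :meth:`RateModel.rhs`."""
    return model.rhs(c)


def analytic_jacobian(model: RateModel, c) -> np.ndarray:
    """Functional form of :meth:`RateModel.jacobian`."""
    return model.jacobian(c)
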