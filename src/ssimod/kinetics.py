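"""Closed-form reaction rate laws and their exact partial derivatives.

All laws share the saturating form v = V_max * C_A^n / (K * e_c + C_A^n * e_u)
with K = K_M^n, e_c = 1 + C_I/K_C and e_u = 1 + C_I/K_U.  With no inhibitor
(e_c = e_u = 1) this is the Hill equation, and with n = 1 the classical
Michaelis-Menten rate.  The mixed (noncompetitive) form generalizes the
competitive (K_U -> inf) and uncompetitive (K_C -> inf) cases.
"""

from __future__ import annotations

import math
from typing import Optional

from .errors import ConfigurationError, DomainError
from .ssi_graph import KineticParams, Reaction

__all__ = [
    "rate_mm",
    "rate_hill",
    "rate_hill_inhibited",
    "rate_partials",
    "reaction_rate",
    "reaction_partials",
]

MM_MODES = ("competitive", "uncompetitive", "noncompetitive")


def _check_conc(name: str, value: float) -> None:
    if not (value >= 0 and math.isfinite(value)):
        raise DomainError(f"{name} must be a finite non-negative concentration, got {value}")


def _check_pos(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise DomainError(f"{name} must be positive and finite, got {value}")


def rate_mm(c_s: float, c_i: float, mode: str, v_max: float, k_m: float,
            k_c: Optional[float] = None, k_u: Optional[float] = None) -> float:
    """Michaelis-Menten rate under reversible inhibition.

    competitive:    v = V_max C_S / (K_M (1 + C_I/K_C) + C_S)
    uncompetitive:  v = V_max C_S / (K_M + C_S (1 + C_I/K_U))
    noncompetitive: v = V_max C_S / (K_M (1 + C_I/K_C) + C_S (1 + C_I/K_U))
    """
    if mode not in MM_MODES:
        raise ValueError(f"unknown inhibition mode {mode!r}")
    _check_conc("c_s", c_s)
    _check_conc("c_i", c_i)
    _check_pos("v_max", v_max)
    _check_pos("k_m", k_m)
    e_c = e_u = 1.0
    if mode in ("competitive", "noncompetitive"):
        _check_pos("k_c", k_c if k_c is not None else 0.0)
        e_c = 1.0 + c_i / k_c
    if mode in ("uncompetitive", "noncompetitive"):
        _check_pos("k_u", k_u if k_u is not None else 0.0)
        e_u = 1.0 + c_i / k_u
    return v_max * c_s / (k_m * e_c + c_s * e_u)


def rate_hill(c_a: float, v_max: float, k: float, n: float) -> float:
    """Hill rate v = V_max C_A^n / (K + C_A^n), with K the saturation
    constant K_M^n.  n = 1 recovers the Michaelis-Menten rate."""
    _check_conc("c_a", c_a)
    _check_pos("v_max", v_max)
    _check_pos("k", k)
    if n < 1:
        raise DomainError(f"Hill coefficient must be >= 1, got {n}")
    cn = c_a ** n
    return v_max * cn / (k + cn)


def rate_hill_inhibited(c_a: float, c_i: float, v_max: float, k: float, n: float,
                        k_c: float, k_u: float) -> float:
    """Mixed-inhibition Hill rate.

    v = V_max C_A^n / (K (1 + C_I/K_C) + C_A^n (1 + C_I/K_U))

    The Hill exponent applies to the substrate only; the inhibitor enters
    linearly through both denominator terms.  At C_I = 0 this reduces exactly
    to :func:`rate_hill`.
    """
    _check_conc("c_a", c_a)
    _check_conc("c_i", c_i)
    _check_pos("v_max", v_max)
    _check_pos("k", k)
    _check_pos("k_c", k_c)
    _check_pos("k_u", k_u)
    if n < 1:
        raise DomainError(f"Hill coefficient must be >= 1, got {n}")
    cn = c_a ** n
    return v_max * cn / (k * (1.0 + c_i / k_c) + cn * (1.0 + c_i / k_u))


def rate_partials(c_a: float, c_i: float, v_max: float, k: float, n: float,
                  k_c: Optional[float] = None,
                  k_u: Optional[float] = None) -> tuple[float, float]:
    """Exact partials (dv/dC_A, dv/dC_I) of the applicable rate law.

    With no inhibitor (k_c and k_u both None) the inhibitor partial is
    identically zero.  dv/dC_A > 0 on the open positive orthant; at
    C_A = 0 with n > 1 the substrate partial is 0.
    """
    _check_conc("c_a", c_a)
    _check_pos("v_max", v_max)
    _check_pos("k", k)
    if n < 1:
        raise DomainError(f"Hill coefficient must be >= 1, got {n}")
    inhibited = k_c is not None or k_u is not None
    if inhibited:
        if k_c is None or k_u is None:
            raise ConfigurationError("an inhibited rate law needs both k_c and k_u")
        _check_conc("c_i", c_i)
        _check_pos("k_c", k_c)
        _check_pos("k_u", k_u)
        e_c = 1.0 + c_i / k_c
        e_u = 1.0 + c_i / k_u
    else:
        e_c = e_u = 1.0
    cn = c_a ** n
    den = k * e_c + cn * e_u
    # d/dC_A [cn / (k e_c + cn e_u)] = n C_A^(n-1) k e_c / den^2
    if c_a == 0.0:
        dva = v_max / (k * e_c) if n == 1 else 0.0
    else:
        dva = v_max * n * c_a ** (n - 1.0) * k * e_c / den ** 2
    if not inhibited:
        return dva, 0.0
    # dv/dC_I = -V_max cn (k/K_C + cn/K_U) / den^2
    dvi = -v_max * cn * (k / k_c + cn / k_u) / den ** 2
    return dva, dvi


# ---------------------------------------------------------------------------
# reaction-level convenience wrappers
# ---------------------------------------------------------------------------

def _single_inhibition_constants(r: Reaction, p: KineticParams) -> tuple[float, float]:
    if len(r.inhibitors) != 1:
        raise ConfigurationError(
            f"reaction {r.id!r} has {len(r.inhibitors)} inhibitors; "
            "rate laws are defined for exactly one"
        )
    inh = r.inhibitors[0]
    try:
        return p.k_c[inh], p.k_u[inh]
    except KeyError as exc:
        raise ConfigurationError(
            f"reaction {r.id!r}: missing inhibition constant for {inh!r}: {exc}"
        ) from None


def reaction_rate(reaction: Reaction, params: KineticParams, c_a: float,
                  c_i: float = 0.0) -> float:
    """Evaluate the rate of one reaction (inhibited form iff it has an
    inhibitor)."""
    if reaction.inhibitors:
        k_c, k_u = _single_inhibition_constants(reaction, params)
        return rate_hill_inhibited(c_a, c_i, params.v_max, params.k, params.n, k_c, k_u)
    return rate_hill(c_a, params.v_max, params.k, params.n)


def reaction_partials(reaction: Reaction, params: KineticParams, c_a: float,
                      c_i: float = 0.0) -> tuple[float, float]:
    """(dv/dC_A, dv/dC_I) for one reaction; inhibitor partial is 0 for an
    uninhibited reaction."""
    if reaction.inhibitors:
        k_c, k_u = _single_inhibition_constants(reaction, params)
        return rate_partials(c_a, c_i, params.v_max, params.k, params.n, k_c, k_u)
    return rate_partials(c_a, 0.0, params.v_max, params.k, params.n)
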