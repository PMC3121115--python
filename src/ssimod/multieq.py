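"""Multistationarity analysis.

Two routes:

* a *structural certificate*: expand det(J) = det(S G) by Cauchy-Binet over
  n-subsets of reactions and each subset determinant over permutations into
  monomials in the rate partials.  On the open positive orthant every partial
  has a fixed strict sign (+ for the substrate, - for an inhibitor) for every
  admissible parameter set, so if all nonzero monomials share one sign the
  Jacobian is nonsingular everywhere and the model cannot admit multiple
  equilibria;

* *numerical search*: multistart damped Newton for positive roots of
  R(C;P) = 0, eigenvalue-based stability classification, and bisection for
  singular-Jacobian witnesses when the certificate is inconclusive.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_build import RateModel
from .ssi_graph import SSIModule, classify_nodes, state_order

__all__ = [
    "CertificateVerdict",
    "EquilibriumRecord",
    "determinant_sign_certificate",
    "cauchy_binet_det",
    "find_equilibria",
    "stability_analysis",
    "find_singular_point",
    "equilibria_to_csv",
]

logger = logging.getLogger(__name__)

MAX_CERTIFICATE_STATES = 8
STABILITY_MARGIN = 1e-9
RESIDUAL_TOL = 1e-10
STEP_TOL = 1e-12
DEDUP_RTOL = 1e-6
POSITIVITY_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# structural certificate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CertificateVerdict:
    """Outcome of the structural determinant-sign analysis.

    ``certified_unique``       all nonzero determinant terms share one sign:
                               det J never vanishes on the positive orthant,
                               hence at most one equilibrium for any P;
    ``inconclusive_mixed_signs`` terms of both signs occur — det J may vanish;
    ``degenerate``             every term is structurally zero (det J == 0);
    ``unsupported``            some reaction has more than one inhibitor.
    """

    status: str
    n_positive: int = 0
    n_negative: int = 0
    n_zero: int = 0
    detail: str = ""
    witness: Optional[np.ndarray] = None

    @property
    def certified(self) -> bool:
        return self.status == "certified_unique"


def _int_det(mat: np.ndarray) -> int:
    """Exact determinant of a small integer matrix by permutation expansion."""
    n = mat.shape[0]
    total = 0
    for perm in itertools.permutations(range(n)):
        prod = 1
        for i, j in enumerate(perm):
            prod *= int(mat[i, j])
            if prod == 0:
                break
        if prod:
            total += _perm_sign(perm) * prod
    return total


def _perm_sign(perm: Sequence[int]) -> int:
    sign = 1
    seen = [False] * len(perm)
    for start in range(len(perm)):
        if seen[start]:
            continue
        length = 0
        j = start
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


def _sign_pattern(module: SSIModule) -> tuple[np.ndarray, np.ndarray]:
    """(S, sigma): stoichiometric matrix and the (m x n) structural sign
    matrix of the rate gradients (+1 substrate, -1 inhibitor, 0 otherwise)."""
    roles = classify_nodes(module).roles
    states = state_order(module)
    index = {s: i for i, s in enumerate(states)}
    n, m = len(states), len(module.reactions)
    s_mat = np.zeros((n, m), dtype=int)
    sigma = np.zeros((m, n), dtype=int)
    for j, r in enumerate(module.reactions):
        if roles[r.substrate] == "state":
            s_mat[index[r.substrate], j] -= 1
            sigma[j, index[r.substrate]] = 1
        if roles[r.product] == "state":
            s_mat[index[r.product], j] += 1
        for i in r.inhibitors:
            if roles[i] == "state":
                sigma[j, index[i]] = -1
    return s_mat, sigma


def determinant_sign_certificate(
    module: SSIModule,
    model: Optional[RateModel] = None,
    witness_seed: int = 0,
) -> CertificateVerdict:
    """Decide whether det J(C;P) has a fixed sign on the positive orthant.

    The expansion treats every rate partial as a free magnitude with a fixed
    strict sign, so a one-signed expansion certifies nonsingularity for *all*
    positive parameter values at once.  When a :class:`RateModel` is supplied
    and the expansion has mixed signs, a numeric singular point is searched
    for and attached as ``witness``.
    """
    if any(len(r.inhibitors) > 1 for r in module.reactions):
        return CertificateVerdict(
            status="unsupported",
            detail="a reaction has more than one inhibitor",
        )
    states = state_order(module)
    n = len(states)
    m = len(module.reactions)
    if n > MAX_CERTIFICATE_STATES:
        raise ValueError(
            f"certificate expansion is combinatorial; refusing n={n} > "
            f"{MAX_CERTIFICATE_STATES} state nodes"
        )
    if m < n:
        return CertificateVerdict(
            status="degenerate",
            detail=f"fewer reactions ({m}) than state nodes ({n}): "
            "det J is identically zero",
        )

    s_mat, sigma = _sign_pattern(module)
    n_pos = n_neg = n_zero = 0
    perms = list(itertools.permutations(range(n)))
    perm_signs = [_perm_sign(p) for p in perms]
    for subset in itertools.combinations(range(m), n):
        det_s = _int_det(s_mat[:, subset])
        if det_s == 0:
            n_zero += len(perms)
            continue
        for perm, psign in zip(perms, perm_signs):
            prod = 1
            for row, col in enumerate(perm):
                prod *= sigma[subset[row], col]
                if prod == 0:
                    break
            if prod == 0:
                n_zero += 1
            elif det_s * psign * prod > 0:
                n_pos += 1
            else:
                n_neg += 1

    if n_pos == 0 and n_neg == 0:
        return CertificateVerdict(
            status="degenerate", n_zero=n_zero,
            detail="every determinant term is structurally zero",
        )
    if n_pos == 0 or n_neg == 0:
        return CertificateVerdict(
            status="certified_unique",
            n_positive=n_pos, n_negative=n_neg, n_zero=n_zero,
            detail="det J has one structural sign on the positive orthant; "
            "no multiple equilibria for any parameter values",
        )
    witness = None
    if model is not None:
        witness = find_singular_point(model, seed=witness_seed)
    return CertificateVerdict(
        status="inconclusive_mixed_signs",
        n_positive=n_pos, n_negative=n_neg, n_zero=n_zero,
        detail="determinant terms of both signs: det J may vanish",
        witness=witness,
    )


def cauchy_binet_det(model: RateModel, c) -> float:
    """det J(C) computed by the Cauchy-Binet expansion over reaction subsets
    (numeric oracle for the structural expansion)."""
    s_mat = model.stoich
    g = model.rate_gradients(c)
    n = model.n_states
    total = 0.0
    for subset in itertools.combinations(range(model.n_reactions), n):
        cols = list(subset)
        total += np.linalg.det(s_mat[:, cols]) * np.linalg.det(g[cols, :])
    return float(total)


# ---------------------------------------------------------------------------
# equilibrium search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumRecord:
    c: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability: str  # asymptotically_stable | unstable | marginal

    def __str__(self) -> str:
        coords = ", ".join(f"{x:.5f}" for x in self.c)
        return f"({coords})  residual={self.residual:.2e}  {self.stability}"


def _damped_newton(model: RateModel, x0: np.ndarray,
                   max_iter: int = 80) -> Optional[np.ndarray]:
    """Damped Newton iteration kept inside the positive orthant.

    Returns a root with residual < RESIDUAL_TOL, or None on failure
    (divergence, singular Jacobian, step collapse).
    """
    x = np.array(x0, dtype=float)
    with np.errstate(all="ignore"):
        r = model.rhs(x)
        rnorm = np.max(np.abs(r))
        for _ in range(max_iter):
            if not np.all(np.isfinite(r)):
                return None
            jac = model.jacobian(x)
            if not np.all(np.isfinite(jac)):
                return None
            try:
                step = np.linalg.solve(jac, -r)
            except np.linalg.LinAlgError:
                logger.debug("abandoning start: singular Jacobian at %s", x)
                return None
            lam = 1.0
            while lam > 1e-6:
                x_new = x + lam * step
                # stay in the (finite) positive orthant
                if np.all(x_new > 0) and np.all(x_new < 1e100):
                    r_new = model.rhs(x_new)
                    new_norm = np.max(np.abs(r_new))
                    if new_norm < rnorm or new_norm < RESIDUAL_TOL:
                        break
                lam *= 0.5
            else:
                return None
            x, r, rnorm = x_new, r_new, new_norm
            if np.max(np.abs(lam * step)) < STEP_TOL * (1.0 + np.max(np.abs(x))):
                break
    return x if rnorm < RESIDUAL_TOL else None


def _lattice_starts(bounds: tuple[float, float], n: int, points: int) -> np.ndarray:
    axis = np.geomspace(bounds[0], bounds[1], points)
    grids = np.meshgrid(*([axis] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def find_equilibria(
    model: RateModel,
    bounds: tuple[float, float] = (1e-3, 1e3),
    n_starts: int = 200,
    seed: int = 0,
    lattice_points: int = 5,
) -> list[EquilibriumRecord]:
    """Multistart damped-Newton search for the positive roots of R(C;P)=0.

    Starts are a deterministic log-spaced lattice (``lattice_points`` per
    axis) followed by ``n_starts`` seeded log-uniform random points in the
    box.  Converged roots are deduplicated at relative tolerance 1e-6,
    restricted to strictly positive coordinates, and returned sorted by the
    second then first state coordinate (a fixed, documented order).
    """
    n = model.n_states
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be a positive box (lo, hi) with lo < hi")
    starts = [_lattice_starts(bounds, n, lattice_points)]
    if n_starts > 0:
        rng = np.random.default_rng(seed)
        starts.append(
            np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts, n)))
        )
    all_starts = np.vstack(starts)
    logger.info(
        "equilibrium search: %d starts, box [%g, %g]^%d, seed %d",
        len(all_starts), lo, hi, n, seed,
    )

    roots: list[np.ndarray] = []
    for x0 in all_starts:
        root = _damped_newton(model, x0)
        if root is None or np.any(root <= POSITIVITY_FLOOR):
            continue
        scale = 1.0 + np.abs(root)
        if not any(
            np.max(np.abs(root - r) / scale) < DEDUP_RTOL for r in roots
        ):
            roots.append(root)

    records = [stability_analysis(model, r) for r in roots]
    if n >= 2:
        records.sort(key=lambda rec: (rec.c[1], rec.c[0]))
    else:
        records.sort(key=lambda rec: rec.c[0])
    return records


def stability_analysis(model: RateModel, c_star) -> EquilibriumRecord:
    """Eigenvalues of the analytic Jacobian at an equilibrium and the
    resulting stability label (margin 1e-9 on real parts)."""
    c_star = np.asarray(c_star, dtype=float)
    residual = float(np.max(np.abs(model.rhs(c_star))))
    jac = model.jacobian(c_star)
    if not np.all(np.isfinite(jac)):
        raise ValueError("non-finite Jacobian entries at the candidate equilibrium")
    eig = np.linalg.eigvals(jac)
    real = eig.real
    if np.all(real < -STABILITY_MARGIN):
        label = "asymptotically_stable"
    elif np.any(real > STABILITY_MARGIN):
        label = "unstable"
    else:
        label = "marginal"
    order = np.argsort(real)
    return EquilibriumRecord(
        c=c_star, residual=residual, eigenvalues=eig[order], stability=label
    )


# ---------------------------------------------------------------------------
# singular-point search
# ---------------------------------------------------------------------------

def find_singular_point(
    model: RateModel,
    c_a=None,
    c_b=None,
    tol: float = 1e-10,
    seed: int = 0,
    n_samples: int = 10_000,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> Optional[np.ndarray]:
    """Locate a state with det J = 0, or return None.

    If ``c_a``/``c_b`` bracket a determinant sign change, bisect the segment;
    otherwise sample the box log-uniformly with the given seed and bisect the
    first sign-discordant pair found.  Absence of a witness is a legitimate
    outcome, not an error.
    """
    det = lambda c: float(np.linalg.det(model.jacobian(c)))

    def _bisect(xa: np.ndarray, xb: np.ndarray) -> Optional[np.ndarray]:
        fa, fb = det(xa), det(xb)
        if fa == 0.0:
            return xa
        if fb == 0.0:
            return xb
        if math.copysign(1.0, fa) == math.copysign(1.0, fb):
            return None
        for _ in range(200):
            xm = 0.5 * (xa + xb)
            fm = det(xm)
            if abs(fm) < tol:
                return xm
            if math.copysign(1.0, fm) == math.copysign(1.0, fa):
                xa, fa = xm, fm
            else:
                xb = xm
        return xm if abs(det(xm)) < tol else None

    if c_a is not None and c_b is not None:
        hit = _bisect(np.asarray(c_a, float), np.asarray(c_b, float))
        if hit is not None:
            return hit

    rng = np.random.default_rng(seed)
    lo, hi = bounds
    samples = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=(n_samples, model.n_states))
    )
    ref = None
    for x in samples:
        d = det(x)
        if d == 0.0:
            return x
        if ref is None:
            ref = (x, d)
        elif math.copysign(1.0, d) != math.copysign(1.0, ref[1]):
            return _bisect(ref[0], x)
    return None


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def equilibria_to_csv(model: RateModel, records: Sequence[EquilibriumRecord]) -> str:
    """One row per equilibrium: coordinates, residual, eigenvalues, label."""
    header = (
        [f"C_{name}" for name in model.states]
        + ["residual"]
        + [f"eig{i + 1}" for i in range(model.n_states)]
        + ["stability"]
    )
    lines = [",".join(header)]
    for rec in records:
        row = (
            [f"{x:.10g}" for x in rec.c]
            + [f"{rec.residual:.3e}"]
            + [
                f"{z.real:.6g}" + (f"{z.imag:+.6g}j" if abs(z.imag) > 1e-12 else "")
                for z in rec.eigenvalues
            ]
            + [rec.stability]
        )
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"
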