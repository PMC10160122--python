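"""Interior equilibrium of the two-patch system.

At a steady state with all populations positive the Leslie-Gower predator
equations force z* = gamma1*x* and w* = gamma2*y*, which reduces the system
to the two prey nullclines.  Eliminating y* leaves a cubic in x*:

    a3*x**3 + b3*x**2 + c3*x + d3 = 0

with, writing R1 = r - sigma1 - q1*E1, R2 = s - sigma2 - q2*E2,
M1 = m1*gamma1 + r/K, M2 = m2*gamma2 + s/L:

    a3 =  M1**2 * M2 / sigma2**2
    b3 = -2 * R1 * M1 * M2 / sigma2**2
    c3 =  R1**2 * M2 / sigma2**2 - M1 * R2 / sigma2
    d3 =  R1 * R2 / sigma2 - sigma1

The published form of c3 has unbalanced parentheses; the
re-derived coefficient above (substitute the x-nullcline into the
y-nullcline and divide through by x) is used by default, and the published
literal variant is available as ``mode="paper_literal"`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import ModelParameters, vector_field

__all__ = [
    "CubicCoefficients",
    "InteriorEquilibrium",
    "ExistenceReport",
    "NoInteriorEquilibrium",
    "cubic_coefficients",
    "existence_conditions",
    "solve_interior_equilibrium",
    "y_from_x",
]

_RESIDUAL_TOL = 1e-8


class NoInteriorEquilibrium(RuntimeError):
    """No positive root of the reduced system yields positive prey in patch 2."""


@dataclass(frozen=True)
class CubicCoefficients:
    a3: float
    b3: float
    c3: float
    d3: float
    mode: str = "derived"

    def as_poly(self) -> np.ndarray:
        return np.array([self.a3, self.b3, self.c3, self.d3])


@dataclass(frozen=True)
class InteriorEquilibrium:
    x_star: float
    y_star: float
    z_star: float
    w_star: float
    residual: float
    from_cubic: int  # index of the cubic root that seeded the solve

    def to_array(self) -> np.ndarray:
        return np.array([self.x_star, self.y_star, self.z_star, self.w_star])


@dataclass(frozen=True)
class ExistenceReport:
    """Truth values of the published existence/uniqueness inequalities.

    Purely descriptive: the solver does not gate on these conditions.
    """

    cond_7a: bool
    cond_7b: bool
    y_positivity_bound: float

    @property
    def unique_claimed(self) -> bool:
        return self.cond_7a and self.cond_7b


def _reduced_constants(p: ModelParameters):
    R1 = p.r - p.sigma1 - p.q1 * p.E1
    R2 = p.s - p.sigma2 - p.q2 * p.E2
    M1 = p.m1 * p.gamma1 + p.r / p.K
    M2 = p.m2 * p.gamma2 + p.s / p.L
    return R1, R2, M1, M2


def _require_migration(p: ModelParameters) -> None:
    if p.sigma2 <= 0:
        raise ValueError("equilibrium reduction divides by sigma2; need sigma2 > 0")


def cubic_coefficients(params: ModelParameters, mode: str = "derived") -> CubicCoefficients:
    """Coefficients of the x*-cubic, sign-normalized so a3 > 0."""
    _require_migration(params)
    R1, R2, M1, M2 = _reduced_constants(params)
    s2 = params.sigma2
    a3 = M1**2 * M2 / s2**2
    b3 = -2.0 * R1 * M1 * M2 / s2**2
    d3 = R1 * R2 / s2 - params.sigma1
    if mode == "derived":
        c3 = R1**2 * M2 / s2**2 - M1 * R2 / s2
    elif mode == "paper_literal":
        # published form, parenthesized exactly as typeset:
        # (1/sigma2^2)*((R1^2 * s/L) + m2*gamma2) - M1*R2/sigma2
        c3 = (R1**2 * (params.s / params.L) + params.m2 * params.gamma2) / s2**2 \
            - M1 * R2 / s2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CubicCoefficients(a3, b3, c3, d3, mode=mode)


def existence_conditions(params: ModelParameters) -> ExistenceReport:
    """Evaluate the two published sufficient inequalities for a unique positive
    root, and the lower bound on x* required for y* > 0."""
    _require_migration(params)
    R1, R2, M1, M2 = _reduced_constants(params)
    cond_7a = R1**2 * M2 < M1 * params.sigma2 * R2
    cond_7b = R2 * R1 < params.sigma1 * params.sigma2
    bound = R1 / M1
    return ExistenceReport(bool(cond_7a), bool(cond_7b), float(bound))


def y_from_x(x_star: float, params: ModelParameters) -> float:
    """Patch-2 prey equilibrium from the patch-1 prey nullcline."""
    R1, _, M1, _ = _reduced_constants(params)
    return x_star * (M1 * x_star - R1) / params.sigma2


def _reduced_system(params: ModelParameters):
    """Prey system after z = gamma1*x, w = gamma2*y substitution."""
    R1, R2, M1, M2 = _reduced_constants(params)

    def F(v):
        x, y = v
        return np.array([
            (R1 - M1 * x) * x + params.sigma2 * y,
            params.sigma1 * x + (R2 - M2 * y) * y,
        ])

    def JF(v):
        x, y = v
        return np.array([
            [R1 - 2.0 * M1 * x, params.sigma2],
            [params.sigma1, R2 - 2.0 * M2 * y],
        ])

    return F, JF


def solve_interior_equilibrium(
    params: ModelParameters,
    *,
    return_all: bool = False,
    refine_tol: float = 1e-12,
    max_iter: int = 50,
):
    """Compute the interior steady state(s) P(x*, y*, z*, w*).

    Positive real roots of the cubic seed a 2-D Newton refinement of the
    reduced prey system; candidates with y* <= 0 are discarded.  Among
    admissible equilibria the one with smallest x* is primary.  Raises
    :class:`NoInteriorEquilibrium` when no admissible root exists.

    With ``return_all=True`` returns the full list (primary first).
    """
    _require_migration(params)
    cubic = cubic_coefficients(params)
    roots = np.roots(cubic.as_poly())  # companion-matrix eigenvalues

    candidates: list[InteriorEquilibrium] = []
    for idx, root in enumerate(roots):
        if abs(root.imag) > 1e-9 * max(1.0, abs(root.real)) or root.real <= 0:
            continue
        x0 = float(root.real)
        y0 = y_from_x(x0, params)
        if y0 <= 0:
            continue
        F, JF = _reduced_system(params)
        v = np.array([x0, y0])
        for _ in range(max_iter):
            f = F(v)
            if np.max(np.abs(f)) < refine_tol:
                break
            step = np.linalg.solve(JF(v), f)
            v = v - step
        x_star, y_star = float(v[0]), float(v[1])
        if x_star <= 0 or y_star <= 0:
            continue
        z_star = params.gamma1 * x_star
        w_star = params.gamma2 * y_star
        residual = float(np.max(np.abs(
            vector_field([x_star, y_star, z_star, w_star], params)
        )))
        if residual > _RESIDUAL_TOL:
            continue
        candidates.append(
            InteriorEquilibrium(x_star, y_star, z_star, w_star, residual, idx)
        )

    # dedupe refined roots that converged to the same point
    unique: list[InteriorEquilibrium] = []
    for c in sorted(candidates, key=lambda e: e.x_star):
        if not unique or abs(c.x_star - unique[-1].x_star) > 1e-8 * max(1.0, c.x_star):
            unique.append(c)

    if not unique:
        raise NoInteriorEquilibrium(
            "no positive cubic root with positive patch-2 prey; the system "
            "has no interior equilibrium for these parameters"
        )
    if return_all:
        return unique
    return unique[0]


def solve_equilibrium_direct(
    params: ModelParameters, x0: float | None = None, y0: float | None = None
) -> InteriorEquilibrium:
    """Independent 2-D root solve of the reduced prey system (no cubic).

    Used as a cross-check oracle against the cubic-seeded path.
    """
    _require_migration(params)
    F, JF = _reduced_system(params)
    if x0 is None:
        # neutral scale-based start
        x0 = params.K / 2.0
    if y0 is None:
        y0 = params.L / 2.0
    sol = optimize.root(F, [x0, y0], jac=JF, method="hybr", tol=1e-13)
    if not sol.success or sol.x[0] <= 0 or sol.x[1] <= 0:
        raise NoInteriorEquilibrium(
            f"direct 2-D solve failed or left the positive quadrant: {sol.message}"
        )
    x_star, y_star = map(float, sol.x)
    z_star = params.gamma1 * x_star
    w_star = params.gamma2 * y_star
    residual = float(np.max(np.abs(
        vector_field([x_star, y_star, z_star, w_star], params)
    )))
    return InteriorEquilibrium(x_star, y_star, z_star, w_star, residual, -1)
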