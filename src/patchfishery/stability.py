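"""Local and global stability of the interior equilibrium.

Local stability goes through the quartic characteristic polynomial

    lambda^4 + a11*lambda^3 + a22*lambda^2 + a33*lambda + a44 = 0

checked with the Routh-Hurwitz conditions, cross-checked against the
eigenvalues of the Jacobian.  Two routes to the coefficients are provided:
``derived`` (from the Jacobian's characteristic polynomial — authoritative)
and ``paper_literal`` (the long printed closed forms, which contain apparent
typos in a33 and a44 and are kept only for comparison reports).

Global stability uses a weighted Volterra-type Lyapunov function

    V = f(x;x*) + l1*f(y;y*) + l2*f(z;z*) + l3*f(w;w*),
    f(u;u*) = u - u* - u*log(u/u*),

whose time derivative is negative when the prey biomasses stay inside the
box (A, B) x (C, D); the bounds and the weights l1 = (y*/x*)(sigma2/sigma1),
l2 = 1/alpha1, l3 = 1/alpha2 are evaluated here, and a Monte-Carlo census
of the sign of dV/dt over the box is reported (not asserted — the published
derivative mixes signs, see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import InteriorEquilibrium
from .model import ModelParameters, jacobian, vector_field

__all__ = [
    "CharPolyCoefficients",
    "StabilityVerdict",
    "LyapunovBounds",
    "jacobian_at",
    "charpoly_coefficients",
    "routh_hurwitz_verdict",
    "eigenvalue_verdict",
    "lyapunov_bounds",
    "lyapunov_value",
    "vdot_diagnostic",
    "vdot_box_census",
]

_MARGIN = 1e-9


@dataclass(frozen=True)
class CharPolyCoefficients:
    a11: float
    a22: float
    a33: float
    a44: float
    aux_a: float  # sigma2*y*/x* + r*x*/K
    aux_b: float  # sigma1*x*/y* + s*y*/L
    mode: str = "derived"

    def as_poly(self) -> np.ndarray:
        return np.array([1.0, self.a11, self.a22, self.a33, self.a44])


@dataclass(frozen=True)
class StabilityVerdict:
    rh_pass: bool
    eigen_pass: bool
    eigenvalues: np.ndarray
    indeterminate: bool

    @property
    def agreement(self) -> bool:
        return self.rh_pass == self.eigen_pass


@dataclass(frozen=True)
class LyapunovBounds:
    A: float
    B: float
    C: float
    D: float
    l1: float
    l2: float
    l3: float


def jacobian_at(params: ModelParameters, eq: InteriorEquilibrium) -> np.ndarray:
    """Analytic Jacobian of the full system at the interior equilibrium."""
    return jacobian(eq.to_array(), params)


def _aux_ab(params: ModelParameters, eq: InteriorEquilibrium) -> tuple[float, float]:
    a = params.sigma2 * eq.y_star / eq.x_star + params.r * eq.x_star / params.K
    b = params.sigma1 * eq.x_star / eq.y_star + params.s * eq.y_star / params.L
    return a, b


def charpoly_coefficients(
    params: ModelParameters, eq: InteriorEquilibrium, mode: str = "derived"
) -> CharPolyCoefficients:
    """Coefficients of the characteristic quartic at the equilibrium.

    ``derived`` computes them from the Jacobian (np.poly on the matrix, i.e.
    from its eigenvalues), so a11 = -trace(J) and a44 = det(J).
    ``paper_literal`` evaluates the printed closed forms; the typo readings
    adopted there are documented in the methods note.
    """
    a, b = _aux_ab(params, eq)
    p = params
    xs, ys = eq.x_star, eq.y_star
    al1, al2 = p.alpha1, p.alpha2
    if mode == "derived":
        coeffs = np.poly(jacobian_at(params, eq))
        _, a11, a22, a33, a44 = map(float, coeffs)
    elif mode == "paper_literal":
        a11 = al1 + al2 + b + a
        a22 = (al1 * al2 + b * al1 + b * al2 + a * b + a * al1
               + p.m1 * al1 * p.gamma1 * xs - p.sigma1 * p.sigma2
               + a * al2 + p.m2 * al2 * p.gamma2 * ys)
        # published "a_1 a1 a2" read as a*alpha1*alpha2; the line break with a
        # missing '+' before "m1 x* b alpha1 gamma1" read as +.
        a33 = (a * al1 * al2 + b * al1 * al2 + a * b * al1 + a * b * al2
               + al1 * al2 * p.m2 * p.gamma2 * ys
               + al1 * al2 * p.m2 * p.gamma2 * ys
               + a * p.m2 * al2 * p.gamma2 * ys
               - al1 * p.sigma1 * p.sigma2 - al2 * p.sigma1 * p.sigma2
               + p.m1 * xs * b * al1 * p.gamma1
               + p.m1 * xs * al1 * al2 * p.gamma1)
        # the alpha1*alpha2*r*sigma1*x*^2/(K y*) term appears twice in the published form; kept
        # twice here, which is part of what the comparison report surfaces.
        a44 = (al1 * al2 * p.r * p.sigma1 * xs**2 / (p.K * ys)
               + (al1 * al2 * p.s * ys / p.L) * (p.r * xs / p.K + p.sigma2 * ys / xs)
               + al1 * al2 * p.r * p.sigma1 * xs**2 / (p.K * ys)
               + (p.sigma2 * al1 * al2 * p.m2 * p.gamma2 * ys**2 / xs
                  + p.r * al1 * al2 * p.m2 * p.gamma2 * xs * ys / p.K)
               + (p.sigma1 * al1 * al2 * p.m1 * p.gamma1 * xs**2 / ys
                  + p.s * al1 * al2 * p.m1 * p.gamma1 * xs * ys / p.L)
               + p.m1 * p.m2 * al1 * al2 * p.gamma1 * p.gamma2 * xs * ys)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CharPolyCoefficients(a11, a22, a33, a44, a, b, mode=mode)


def charpoly_comparison(
    params: ModelParameters, eq: InteriorEquilibrium
) -> dict[str, dict[str, float]]:
    """Per-coefficient relative difference between derived and published forms."""
    d = charpoly_coefficients(params, eq, mode="derived")
    lit = charpoly_coefficients(params, eq, mode="paper_literal")
    report = {}
    for name in ("a11", "a22", "a33", "a44"):
        dv, lv = getattr(d, name), getattr(lit, name)
        denom = max(abs(dv), abs(lv), 1e-300)
        report[name] = {
            "derived": dv,
            "paper_literal": lv,
            "rel_difference": abs(dv - lv) / denom,
        }
    return report


def routh_hurwitz_verdict(c: CharPolyCoefficients) -> bool:
    """The five published Routh-Hurwitz conditions for the quartic, verbatim."""
    return bool(
        c.a11 > 0
        and c.a33 > 0
        and c.a44 > 0
        and c.a33 * (c.a11 * c.a22 - c.a33) > c.a11**2 * c.a44
        and c.a44 * (c.a11 * c.a22 * c.a33 - c.a11**2 * c.a44 - c.a33**2) > 0
    )


def eigenvalue_verdict(J: np.ndarray, rh_pass: bool | None = None) -> StabilityVerdict:
    """Stability from the eigenvalues of ``J`` (all real parts < 0).

    When any real part lies within 1e-9 of zero the verdict is flagged
    ``indeterminate`` and no agreement with Routh-Hurwitz is required.
    """
    eigenvalues = np.linalg.eigvals(np.asarray(J, dtype=float))
    reals = eigenvalues.real
    eigen_pass = bool(np.all(reals < 0))
    indeterminate = bool(np.any(np.abs(reals) < _MARGIN))
    if rh_pass is None:
        rh_pass = eigen_pass
    return StabilityVerdict(bool(rh_pass), eigen_pass, eigenvalues, indeterminate)


def stability_verdict(
    params: ModelParameters, eq: InteriorEquilibrium
) -> StabilityVerdict:
    """Combined Routh-Hurwitz + eigenvalue verdict at the equilibrium."""
    c = charpoly_coefficients(params, eq)
    return eigenvalue_verdict(jacobian_at(params, eq), routh_hurwitz_verdict(c))


def lyapunov_bounds(params: ModelParameters, eq: InteriorEquilibrium) -> LyapunovBounds:
    """Prey-biomass box (A, B) x (C, D) and the Lyapunov weights."""
    p = params
    c = p.r / (p.m1 * p.K * p.gamma1)
    root_c = np.sqrt(4.0 * c + 4.0 * c**2)
    A = (1.0 + 2.0 * c - root_c) / p.m1
    B = (1.0 + 2.0 * c + root_c) / p.m1
    d = p.s / (p.L * p.gamma2 * p.m2)
    root_d = np.sqrt(4.0 * d + 4.0 * d**2)
    pref = p.sigma1 * eq.x_star / (p.m2 * p.sigma2 * eq.y_star)
    C = pref * (1.0 + 2.0 * d - root_d)
    D = pref * (1.0 + 2.0 * d + root_d)
    l1 = (eq.y_star / eq.x_star) * (p.sigma2 / p.sigma1)
    l2 = 1.0 / p.alpha1
    l3 = 1.0 / p.alpha2
    return LyapunovBounds(float(A), float(B), float(C), float(D), l1, l2, l3)


def _entropy_term(u: np.ndarray, u_star: float) -> np.ndarray:
    return u - u_star - u_star * np.log(u / u_star)


def lyapunov_value(state, eq: InteriorEquilibrium, params: ModelParameters) -> float:
    """V(state): weighted sum of u - u* - u*log(u/u*) terms; zero at the
    equilibrium, strictly positive elsewhere in the positive orthant."""
    u = np.asarray(state, dtype=float)
    if np.any(u <= 0):
        raise ValueError("Lyapunov function defined only for positive states")
    lb = lyapunov_bounds(params, eq)
    weights = np.array([1.0, lb.l1, lb.l2, lb.l3])
    terms = _entropy_term(u, eq.to_array())
    return float(np.dot(weights, terms))


def vdot_diagnostic(state, eq: InteriorEquilibrium, params: ModelParameters) -> float:
    """dV/dt along the flow: grad(V) . f at ``state``."""
    u = np.asarray(state, dtype=float)
    if np.any(u <= 0):
        raise ValueError("dV/dt defined only for positive states")
    lb = lyapunov_bounds(params, eq)
    weights = np.array([1.0, lb.l1, lb.l2, lb.l3])
    grad = weights * (1.0 - eq.to_array() / u)
    return float(np.dot(grad, vector_field(u, params)))


def vdot_box_census(
    params: ModelParameters,
    eq: InteriorEquilibrium,
    n_samples: int = 10_000,
    seed: int = 0,
    predator_band: tuple[float, float] = (0.5, 1.5),
) -> dict[str, float]:
    """Sign distribution of dV/dt over the Lyapunov box.

    Prey are sampled uniformly in (A, B) x (C, D); the theorem constrains
    only prey, so predators are sampled in ``predator_band`` times their
    equilibrium values.  Returns fractions, reported rather than asserted.
    """
    lb = lyapunov_bounds(params, eq)
    rng = np.random.default_rng(seed)
    xs = rng.uniform(max(lb.A, 1e-9), lb.B, n_samples)
    ys = rng.uniform(max(lb.C, 1e-9), lb.D, n_samples)
    zs = rng.uniform(predator_band[0] * eq.z_star, predator_band[1] * eq.z_star, n_samples)
    ws = rng.uniform(predator_band[0] * eq.w_star, predator_band[1] * eq.w_star, n_samples)
    vals = np.array([
        vdot_diagnostic([x, y, z, w], eq, params)
        for x, y, z, w in zip(xs, ys, zs, ws)
    ])
    return {
        "n": float(n_samples),
        "frac_negative": float(np.mean(vals < 0)),
        "frac_positive": float(np.mean(vals > 0)),
        "max_vdot": float(vals.max()),
        "min_vdot": float(vals.min()),
    }
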