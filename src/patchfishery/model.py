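"""Core model: parameters, state, and the deterministic two-patch vector field.

The model describes prey biomass ``x`` (patch 1) and ``y`` (patch 2) growing
logistically, migrating between patches at rates ``sigma1`` (1->2) and
``sigma2`` (2->1), harvested with efforts ``E1``, ``E2`` and catchabilities
``q1``, ``q2``, and consumed by patch-resident predators ``z``, ``w`` whose
growth is of Leslie-Gower type: predator carrying capacity is proportional
(``gamma1``, ``gamma2``) to local prey abundance.

    x' = phi1(x, z) * x + sigma2 * y
    y' = sigma1 * x + phi2(y, w) * y
    z' = phi3(x, z)
    w' = phi4(y, w)

with

    phi1 = r - sigma1 - q1*E1 - m1*z - r*x/K
    phi2 = s - sigma2 - q2*E2 - m2*w - s*y/L
    phi3 = alpha1*z - alpha1*z**2 / (gamma1*x)
    phi4 = alpha2*w - alpha2*w**2 / (gamma2*y)

Note the asymmetry inherited from the published formulation: the prey growth terms
phi1, phi2 multiply the prey biomass, while the predator terms phi3, phi4
enter as whole right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "StateVector",
    "Trajectory",
    "PARAMETER_NAMES",
    "phi",
    "vector_field",
    "jacobian",
    "simulate_ode",
    "POSITIVITY_FLOOR",
]

#: Prey biomass below this value makes the predator equations (z^2/x, w^2/y)
#: numerically meaningless; integrators halt (ODE) or clamp-and-count (SDE).
POSITIVITY_FLOOR = 1e-12

PARAMETER_NAMES = (
    "r", "s", "sigma1", "sigma2", "q1", "q2", "E1", "E2",
    "m1", "m2", "gamma1", "gamma2", "K", "L", "alpha1", "alpha2",
)

# migration and predation rates may be zero (decoupled / predator-free
# reductions); everything else must be strictly positive.
_NONNEG_OK = {"sigma1", "sigma2", "m1", "m2"}


class AdmissibilityError(ValueError):
    """State left the domain on which the vector field is defined."""


@dataclass(frozen=True)
class ModelParameters:
    """The 16 ecological and harvesting constants of the two-patch model.

    Units: rates r, s, sigma1, sigma2, alpha1, alpha2 are 1/time; q1, q2 are
    1/(effort*time); E1, E2 are effort; m1, m2 are 1/(predator*time);
    gamma1, gamma2 dimensionless; K, L biomass.
    """

    r: float
    s: float
    sigma1: float
    sigma2: float
    q1: float
    q2: float
    E1: float
    E2: float
    m1: float
    m2: float
    gamma1: float
    gamma2: float
    K: float
    L: float
    alpha1: float
    alpha2: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if name in _NONNEG_OK:
                if value < 0:
                    raise ValueError(f"parameter {name} must be >= 0, got {value}")
            elif value <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "ModelParameters":
        unknown = set(mapping) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class StateVector:
    """Biomass of (prey-1, prey-2, predator-1, predator-2)."""

    x: float
    y: float
    z: float
    w: float

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.w], dtype=float)

    @classmethod
    def from_array(cls, u: np.ndarray) -> "StateVector":
        x, y, z, w = np.asarray(u, dtype=float)
        return cls(x, y, z, w)


@dataclass
class Trajectory:
    """Time series of the four populations with solver metadata.

    ``states`` has shape (len(times), 4), columns (x, y, z, w).
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a non-empty 1-D sequence")
        if self.states.shape != (len(self.times), 4):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"({len(self.times)}, 4)"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def _check_admissible(x: float, y: float) -> None:
    if x <= 0:
        raise AdmissibilityError(
            f"prey biomass x={x} is non-positive; the predator term "
            "alpha1*z**2/(gamma1*x) is singular at x=0"
        )
    if y <= 0:
        raise AdmissibilityError(
            f"prey biomass y={y} is non-positive; the predator term "
            "alpha2*w**2/(gamma2*y) is singular at y=0"
        )


def phi(state, params: ModelParameters) -> np.ndarray:
    """The four growth functionals (phi1, phi2, phi3, phi4) at ``state``."""
    x, y, z, w = _as_array(state)
    p = params
    phi1 = p.r - p.sigma1 - p.q1 * p.E1 - p.m1 * z - p.r * x / p.K
    phi2 = p.s - p.sigma2 - p.q2 * p.E2 - p.m2 * w - p.s * y / p.L
    # factorized alpha*z*(1 - z/(gamma*x)) form: vanishes exactly on the
    # predator nullclines z = gamma1*x, w = gamma2*y
    phi3 = p.alpha1 * z * (1.0 - z / (p.gamma1 * x))
    phi4 = p.alpha2 * w * (1.0 - w / (p.gamma2 * y))
    return np.array([phi1, phi2, phi3, phi4])


def _as_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    u = np.asarray(state, dtype=float)
    if u.shape != (4,):
        raise ValueError(f"state must have 4 components, got shape {u.shape}")
    return u


def vector_field(state, params: ModelParameters) -> np.ndarray:
    """Time derivative (x', y', z', w') of the noise-free system."""
    u = _as_array(state)
    _check_admissible(u[0], u[1])
    p1, p2, p3, p4 = phi(u, params)
    return np.array([
        p1 * u[0] + params.sigma2 * u[1],
        params.sigma1 * u[0] + p2 * u[1],
        p3,
        p4,
    ])


def jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field` at ``state``."""
    x, y, z, w = _as_array(state)
    _check_admissible(x, y)
    p = params
    J = np.zeros((4, 4))
    J[0, 0] = p.r - p.sigma1 - p.q1 * p.E1 - p.m1 * z - 2 * p.r * x / p.K
    J[0, 1] = p.sigma2
    J[0, 2] = -p.m1 * x
    J[1, 0] = p.sigma1
    J[1, 1] = p.s - p.sigma2 - p.q2 * p.E2 - p.m2 * w - 2 * p.s * y / p.L
    J[1, 3] = -p.m2 * y
    J[2, 0] = p.alpha1 * z**2 / (p.gamma1 * x**2)
    J[2, 2] = p.alpha1 - 2 * p.alpha1 * z / (p.gamma1 * x)
    J[3, 1] = p.alpha2 * w**2 / (p.gamma2 * y**2)
    J[3, 3] = p.alpha2 - 2 * p.alpha2 * w / (p.gamma2 * y)
    return J


def rk4_step(f: Callable[[np.ndarray], np.ndarray], u: np.ndarray, dt: float) -> np.ndarray:
    """One classical Runge-Kutta step; shared with the delay integrator so the
    tau=0 reduction is exact."""
    k1 = f(u)
    k2 = f(u + 0.5 * dt * k1)
    k3 = f(u + 0.5 * dt * k2)
    k4 = f(u + dt * k3)
    return u + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_ode(
    params: ModelParameters,
    init,
    t_end: float,
    dt: float = 0.01,
    *,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the noise-free system from ``init`` to ``t_end``.

    ``method="adaptive"`` uses an adaptive Runge-Kutta (RK45) with dense
    output sampled every ``dt``; ``method="rk4"`` uses fixed-step classical
    RK4 (for exact comparability with the stochastic and delayed steppers).
    Integration halts with a diagnostic if prey biomass falls to the
    positivity floor.
    """
    u0 = _as_array(init)
    _check_admissible(u0[0], u0[1])
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end == 0:
        return Trajectory(
            np.array([0.0]), u0[None, :],
            meta={"solver": method, "dt": dt, "floor_events": 0},
        )

    if method == "adaptive":
        def rhs(t, u):
            return vector_field(u, params)

        def prey_floor(t, u):
            return min(u[0], u[1]) - POSITIVITY_FLOOR

        prey_floor.terminal = True
        prey_floor.direction = -1
        times = np.arange(0.0, t_end + 0.5 * dt, dt)
        times[-1] = min(times[-1], t_end)
        sol = solve_ivp(
            rhs, (0.0, t_end), u0, method="RK45", rtol=rtol, atol=atol,
            dense_output=True, events=prey_floor,
        )
        if sol.status == 1:
            t_stop = float(sol.t_events[0][0])
            raise AdmissibilityError(
                f"prey biomass reached the positivity floor at t={t_stop:.6g}; "
                "trajectory left the admissible domain"
            )
        if sol.status != 0:
            raise RuntimeError(f"integration failed: {sol.message}")
        states = sol.sol(times).T
        meta = {"solver": "RK45", "dt": dt, "rtol": rtol, "atol": atol,
                "floor_events": 0, "nfev": int(sol.nfev)}
        return Trajectory(times, states, meta)

    if method == "rk4":
        n = int(round(t_end / dt))
        times = np.linspace(0.0, n * dt, n + 1)
        states = np.empty((n + 1, 4))
        states[0] = u0
        f = lambda u: vector_field(u, params)
        for i in range(n):
            states[i + 1] = rk4_step(f, states[i], dt)
            if states[i + 1, 0] <= POSITIVITY_FLOOR or states[i + 1, 1] <= POSITIVITY_FLOOR:
                raise AdmissibilityError(
                    f"prey biomass reached the positivity floor at t={times[i + 1]:.6g}"
                )
        return Trajectory(times, states,
                          meta={"solver": "rk4", "dt": dt, "floor_events": 0})

    raise ValueError(f"unknown method {method!r}; use 'adaptive' or 'rk4'")
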