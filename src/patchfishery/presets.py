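"""Built-in parameter scenarios and the random-parameter sampler.

Two presets ship because the published parameter tables disagree on four entries
(s, gamma2, E1, E2):

* ``table1`` — the tabulated parameter description values.  The stochastic
  noise-intensity experiments and the delay experiments use this set.
* ``figset`` — the set listed in the numerical-simulation text, used for
  the deterministic time-series figures and the spectral examples.

Every report produced by the package names the preset used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, StateVector

__all__ = ["ScenarioPreset", "preset", "available_presets", "sample_random_parameters"]

_COMMON = dict(
    r=3.0, sigma1=1.8, sigma2=1.6, q1=0.5, q2=0.7,
    m1=1.2, m2=1.8, gamma1=0.5, K=10.0, L=15.0,
    alpha1=0.5, alpha2=0.8,
)

_PRESETS = {
    "table1": dict(_COMMON, s=2.8, gamma2=0.3, E1=2.5, E2=3.5),
    "figset": dict(_COMMON, s=3.2, gamma2=0.2, E1=0.9, E2=1.2),
}

#: Default initial biomass for time-series runs (prey-1, prey-2, pred-1,
#: pred-2).  The source figure caption is ambiguous about initial values;
#: these are the adopted defaults.
DEFAULT_INIT = StateVector(7.0, 10.0, 12.0, 15.0)


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    params: ModelParameters
    default_init: StateVector


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ScenarioPreset:
    """Look up a built-in scenario by name (``table1`` or ``figset``)."""
    try:
        values = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {available_presets()}"
        ) from None
    return ScenarioPreset(name, ModelParameters(**values), DEFAULT_INIT)


def sample_random_parameters(
    seed: int,
    n: int,
    *,
    decades: float = 1.0,
    require_equilibrium: bool = True,
    max_draws: int | None = None,
) -> list[ModelParameters]:
    """Draw ``n`` random parameter sets, log-uniform within ``decades``
    decades of the ``figset`` values.

    With ``require_equilibrium`` (default), sets that do not admit a
    positive interior equilibrium are rejected; the retention fraction is
    available via :func:`sampling_report`.  Deterministic in ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .equilibrium import solve_interior_equilibrium, NoInteriorEquilibrium

    rng = np.random.default_rng(seed)
    base = preset("figset").params.to_dict()
    names = list(base)
    out: list[ModelParameters] = []
    draws = 0
    limit = max_draws if max_draws is not None else 200 * n
    while len(out) < n and draws < limit:
        draws += 1
        factors = 10.0 ** rng.uniform(-decades, decades, size=len(names))
        candidate = ModelParameters(
            **{k: base[k] * f for k, f in zip(names, factors)}
        )
        if require_equilibrium:
            try:
                solve_interior_equilibrium(candidate)
            except (NoInteriorEquilibrium, RuntimeError):
                continue
        out.append(candidate)
    if len(out) < n:
        raise RuntimeError(
            f"sampler retained only {len(out)}/{n} sets after {draws} draws"
        )
    sample_random_parameters.last_retention = len(out) / draws
    return out
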