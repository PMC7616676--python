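"""Intracellular stress-response dynamics.

Oxidative variant: H2O2 entering the cell oxidises the transcription factor
OxyR; oxidised OxyR induces the scavengers KatG (catalase) and AhpC
(peroxidase) and the glutaredoxin GrxA, which re-reduces OxyR
(Michaelis-Menten kinetics throughout, first-order dilution by growth).
General variant: an abstract toxin induces a single detoxifying enzyme.

Both variants expose the raw right-hand sides, a deterministic integrator over
one outer time step (stressor concentration and elongation rate held fixed),
and - for the oxidative variant - a Langevin (Euler-Maruyama) stochastic step
in growth-rate-non-dimensionalised time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import CellState, ModelParameters

__all__ = [
    "NoiseConfig",
    "oxidative_derivatives",
    "general_derivatives",
    "integrate_response",
    "stochastic_step",
    "integrate_cells",
    "stochastic_step_cells",
    "unstressed_steady_state",
    "DEFAULT_N_SUB",
]

DEFAULT_N_SUB = 100  # fixed sub-steps per outer step for the deterministic path


@dataclass
class NoiseConfig:
    """Langevin noise settings for the stochastic oxidative model."""

    enabled: bool = True
    sigma_OxyR: float = 0.0002
    sigma_GrxA: float = 0.02
    sigma_KatG: float = 0.02
    sigma_AhpC: float = 0.02
    dt_nd: float = 5e-6  # non-dimensional inner step
    rng_seed: int | None = None
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dt_nd <= 0:
            raise ValueError("dt_nd must be > 0")
        if min(self.sigma_OxyR, self.sigma_GrxA, self.sigma_KatG, self.sigma_AhpC) < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def from_params(cls, params: ModelParameters, rng_seed=None) -> "NoiseConfig":
        return cls(
            sigma_OxyR=params.sigma_OxyR,
            sigma_GrxA=params.sigma_GrxA,
            sigma_KatG=params.sigma_KatG,
            sigma_AhpC=params.sigma_AhpC,
            dt_nd=params.dt_nd,
            rng_seed=rng_seed,
        )

    @property
    def sigmas(self) -> np.ndarray:
        return np.array(
            [self.sigma_OxyR, self.sigma_GrxA, self.sigma_KatG, self.sigma_AhpC]
        )

    @property
    def rng(self) -> np.random.Generator:
        if self._rng is None:
            self._rng = np.random.default_rng(self.rng_seed)
        return self._rng


def _pack_ox(params: ModelParameters) -> np.ndarray:
    return np.array(
        [
            params.K_ox,
            params.K_red,
            params.h_OxyR,
            params.OxyR_total,
            params.R_grxA_basal,
            params.K_grxA_act,
            params.h_grxA_act,
            params.R_katG_basal,
            params.K_katG_act,
            params.h_katG_act,
            params.R_ahpC_basal,
            params.K_ahpC_act,
            params.h_ahpC_act,
            params.K_AhpC,
            params.h_AhpC,
            params.K_KatG,
            params.h_KatG,
            params.R_H2O2_basal,
            params.R_influx,
        ]
    )


def _pack_gen(params: ModelParameters) -> np.ndarray:
    return np.array(
        [params.R_influx_tox, params.K_cat, params.h_E, params.K_act, params.h_act]
    )


def oxidative_derivatives(
    state: CellState, h_ext: float, g: float, params: ModelParameters
) -> np.ndarray:
    """Right-hand side of the OxyR regulon ODEs (uM/min).

    Returns d/dt of [OxyR_red, GrxA, KatG, AhpC, H2O2_cell] with the external
    concentration ``h_ext`` and elongation rate ``g`` held fixed.
    """
    if h_ext < 0 or g < 0:
        raise ValueError("h_ext and g must be >= 0")
    if state.OxyR_red > params.OxyR_total * (1 + 1e-12):
        raise ValueError(
            f"state corruption: OxyR_red={state.OxyR_red} exceeds "
            f"OxyR_total={params.OxyR_total}"
        )
    y = state.species_vector("oxidative")
    return oxidative_rhs(y, h_ext, g, params)


def oxidative_rhs(
    y: np.ndarray, h_ext: float, g: float, params: ModelParameters
) -> np.ndarray:
    """Vector RHS on a raw state array (used by integrators and root finders)."""
    oxy_red, grxA, katG, ahpC, H = y
    ox = max(params.OxyR_total - oxy_red, 0.0)
    red_frac = ox / (ox + params.h_OxyR)
    d = np.empty(5)
    d[0] = -params.K_ox * oxy_red * H + params.K_red * grxA * red_frac
    d[1] = (
        params.R_grxA_basal
        + params.K_grxA_act * ox / (ox + params.h_grxA_act)
        - g * grxA
    )
    d[2] = (
        params.R_katG_basal
        + params.K_katG_act * ox / (ox + params.h_katG_act)
        - g * katG
    )
    d[3] = (
        params.R_ahpC_basal
        + params.K_ahpC_act * ox / (ox + params.h_ahpC_act)
        - g * ahpC
    )
    d[4] = (
        params.R_influx * h_ext
        + params.R_H2O2_basal
        - params.K_AhpC * ahpC * H / (H + params.h_AhpC)
        - params.K_KatG * katG * H / (H + params.h_KatG)
    )
    return d


def general_derivatives(
    toxin_cell: float,
    enzyme: float,
    toxin_ext: float,
    g: float,
    params: ModelParameters,
) -> np.ndarray:
    """Right-hand side of the general toxin-response ODEs (a.u./min)."""
    if min(toxin_cell, enzyme, toxin_ext, g) < 0:
        raise ValueError("concentrations and g must be >= 0")
    dT = params.R_influx_tox * toxin_ext - params.K_cat * enzyme * (
        toxin_cell / (toxin_cell + params.h_E)
    )
    dE = params.K_act * (toxin_cell / (toxin_cell + params.h_act)) - g * enzyme
    return np.array([dT, dE])


def integrate_cells(
    Y: np.ndarray,
    h_ext: np.ndarray,
    g: np.ndarray,
    params: ModelParameters,
    dt: float,
    n_sub: int = DEFAULT_N_SUB,
) -> np.ndarray:
    """Advance a (n_cells, n_species) state array by ``dt`` in place."""
    p = _pack_ox(params) if params.variant == "oxidative" else _pack_gen(params)
    if params.variant == "oxidative":
        return _kernels.ox_integrate_cells(Y, h_ext, g, p, dt, n_sub)
    return _kernels.gen_integrate_cells(Y, h_ext, g, p, dt, n_sub)


def integrate_response(
    state: CellState,
    h_ext: float,
    g: float,
    dt: float,
    params: ModelParameters,
    n_sub: int = DEFAULT_N_SUB,
) -> CellState:
    """Advance one cell's response by ``dt`` with ``h_ext`` and ``g`` fixed.

    All concentrations are kept >= 0 and OxyR_red <= OxyR_total. dt = 0 is the
    identity.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return state.with_species(state.species_vector(params.variant), params.variant)
    Y = state.species_vector(params.variant)[None, :].copy()
    integrate_cells(
        Y, np.array([float(h_ext)]), np.array([float(g)]), params, dt, n_sub
    )
    if not np.all(np.isfinite(Y)):
        raise ArithmeticError(
            f"response integration failed (non-finite state) at h_ext={h_ext}, g={g}"
        )
    return state.with_species(Y[0], params.variant)


def n_inner_steps(g: float, dt: float, dt_nd: float) -> int:
    """Inner Euler-Maruyama steps so that each advances ~dt_nd of g*t time."""
    return max(1, int(math.ceil(g * dt / dt_nd)))


def stochastic_step_cells(
    Y: np.ndarray,
    h_ext: np.ndarray,
    g: np.ndarray,
    params: ModelParameters,
    dt: float,
    noise: NoiseConfig,
) -> np.ndarray:
    """Euler-Maruyama step for an array of cells (oxidative variant only)."""
    if params.variant != "oxidative":
        raise NotImplementedError("the stochastic variant is defined for the "
                                  "oxidative model only")
    g = np.maximum(np.asarray(g, dtype=float), 1e-12)  # stalled cells: noise -> 0
    n_inner = np.array([n_inner_steps(gi, dt, noise.dt_nd) for gi in g])
    Z = noise.rng.standard_normal((Y.shape[0], int(n_inner.max()), 4))
    return _kernels.ox_sde_cells(
        Y, np.asarray(h_ext, dtype=float), g, _pack_ox(params), noise.sigmas, dt,
        n_inner, Z,
    )


def stochastic_step(
    state: CellState,
    h_ext: float,
    g: float,
    noise: NoiseConfig,
    params: ModelParameters,
    dt: float = 1.0,
) -> CellState:
    """Advance one cell by ``dt`` with Langevin gene-expression noise.

    The gene equations are non-dimensionalised in time (t_nd = t * g) and
    advanced with inner step dt_nd; each inner step adds sigma*Z*sqrt(dt_nd)
    to its species. H2O2 is co-integrated deterministically. Reproducible for
    a fixed ``noise.rng_seed``.
    """
    if not noise.enabled:
        return integrate_response(state, h_ext, g, dt, params)
    if g <= 0:
        raise ValueError(
            "non-dimensionalisation undefined: g must be > 0 with noise enabled"
        )
    if h_ext < 0:
        raise ValueError("h_ext must be >= 0")
    Y = state.species_vector("oxidative")[None, :].copy()
    stochastic_step_cells(Y, np.array([h_ext]), np.array([g]), params, dt, noise)
    return state.with_species(Y[0], "oxidative")


def unstressed_steady_state(params: ModelParameters) -> np.ndarray:
    """Fixed point of the response at zero external stressor and g = g0.

    Used as the initial condition for simulations, so that the pre-treatment
    phase starts at (not merely near) the unstressed equilibrium.
    """
    from scipy.optimize import root

    if params.variant == "general":
        return np.zeros(2)  # quiescent fixed point: no toxin, no enzyme

    def rhs(y):
        return oxidative_rhs(np.maximum(y, 0.0), 0.0, params.g0, params)

    ahpC0 = (params.R_ahpC_basal + 1e-6) / params.g0
    y0 = np.array([params.OxyR_total, 1e-3, 1e-3, ahpC0, 1e-6])
    sol = root(rhs, y0, method="hybr", tol=1e-12)
    y = np.clip(sol.x, 0.0, None)
    y[0] = min(y[0], params.OxyR_total)
    if not sol.success or np.max(np.abs(rhs(y))) > 1e-8:
        raise ArithmeticError("failed to locate the unstressed steady state")
    return y
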