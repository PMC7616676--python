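"""Shared domain types and published parameter sets.

All kinetics run in micromolar (uM) and minutes; lengths in micrometres (um).
Literature constants quoted per second are converted once, at parameter
construction, via :func:`per_second_to_per_minute`. The general (abstract toxin)
model uses arbitrary units (a.u.) for concentrations; there is no cross
conversion between a.u. and uM.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "CellState",
    "TrenchState",
    "Trace",
    "default_parameters",
    "per_second_to_per_minute",
    "save_config",
    "load_config",
    "ConfigError",
]

#: mean elongation rates without H2O2, per growth medium (1/min)
G0_BY_MEDIUM = {"glycerol": 0.025, "glucose": 0.042, "glucose_LB": 0.065}

_M2_PER_S_TO_UM2_PER_MIN = 1e12 * 60.0  # m^2/s -> um^2/min
_M_PER_S_TO_UM_PER_MIN = 1e6 * 60.0  # m/s -> um/min


class ConfigError(ValueError):
    """Invalid configuration: unknown variant/medium, unknown keys, bad values."""


def per_second_to_per_minute(rate: float) -> float:
    """Convert a non-negative per-second rate to per-minute (x 60)."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return rate * 60.0


@dataclass
class ModelParameters:
    """Every rate constant, geometry value and noise amplitude of the model.

    Defaults are the published oxidative-stress parameter set for M9 glucose,
    with all literature per-second rates already converted to per-minute.
    """

    variant: str = "oxidative"  # {"oxidative", "general"}
    medium: str = "glucose"  # {"glycerol", "glucose", "glucose_LB"}

    # growth model
    g0: float = 0.042  # baseline elongation rate (1/min)
    c1: float = 2e4  # growth-inhibition steepness (1/uM)
    c2: float = 1e-4  # half-inhibition intracellular H2O2 (uM)
    L_div: float = 2.0  # added-length division threshold (um)

    # geometry / cell-cell interaction
    L_trench: float = 25.0  # trench length (um)
    W: float = 1.2  # trench width (um), square cross-section
    R_c: float = 0.575  # cell radius (um)
    D: float = 1e-9 * _M2_PER_S_TO_UM2_PER_MIN  # H2O2 diffusion (um^2/min)
    k_abs: float = 1.6e-5 * _M_PER_S_TO_UM_PER_MIN  # envelope absorption (um/min)

    # OxyR redox cycle
    K_ox: float = per_second_to_per_minute(0.1)  # OxyR oxidation (1/uM/min)
    K_red: float = per_second_to_per_minute(8.0)  # OxyR reduction by GrxA (1/min)
    h_OxyR: float = 2583.0  # Michaelis constant of OxyR reduction (uM)
    OxyR_total: float = 1.0  # total OxyR (uM)

    # gene expression (basal + OxyR-Ox-inducible)
    R_grxA_basal: float = 0.0  # uM/min
    R_katG_basal: float = 0.0  # uM/min
    R_ahpC_basal: float = 0.01  # uM/min
    K_grxA_act: float = 0.1  # uM/min
    K_katG_act: float = 0.15  # uM/min
    K_ahpC_act: float = 0.2  # uM/min
    h_grxA_act: float = 0.1  # uM
    h_katG_act: float = 0.18  # uM
    h_ahpC_act: float = 0.1  # uM

    # H2O2 scavenging and balance
    K_AhpC: float = per_second_to_per_minute(660.0)  # 1/min
    K_KatG: float = per_second_to_per_minute(490000.0)  # 1/min
    h_AhpC: float = 1.2  # uM
    h_KatG: float = 5900.0  # uM
    R_H2O2_basal: float = 0.02  # endogenous H2O2 production (uM/min)
    R_influx: float = 1.0  # H2O2 influx rate constant (1/min)

    # Langevin noise (dimensionless, per non-dimensional time)
    sigma_OxyR: float = 0.0002
    sigma_GrxA: float = 0.02
    sigma_KatG: float = 0.02
    sigma_AhpC: float = 0.02
    dt_nd: float = 5e-6  # non-dimensional SDE inner step

    # simulation bookkeeping
    dt: float = 1.0  # outer time step (min)
    t_treat: int = 50  # treatment onset time point
    n_trenches: int = 3  # ensemble size
    k_GrxA_calibration: float = 1150.0  # model-to-reporter intensity scale

    # general (abstract toxin) model fields, a.u.
    K_cat: float = 10.0  # detox catalytic rate (1/min)
    h_E: float = 1.0  # detox Michaelis constant (a.u.)
    K_act: float = 0.1  # maximal enzyme expression rate (a.u./min)
    h_act: float = 1.0  # half-induction toxin level (a.u.)
    R_influx_tox: float = 1.0  # toxin influx (1/min)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        strictly_positive = ("g0", "dt", "L_div", "L_trench", "W", "R_c")
        for name in strictly_positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ConfigError(f"{f.name} must be >= 0, got {v}")
        if 2 * self.R_c >= self.W:
            raise ConfigError(
                f"cell diameter 2*R_c={2 * self.R_c} must be < trench width W={self.W}"
            )
        if self.L_div > self.L_trench:
            raise ConfigError("L_div must be <= L_trench")
        if self.variant not in ("oxidative", "general"):
            raise ConfigError(f"unknown variant {self.variant!r}")

    @property
    def sigmas(self) -> np.ndarray:
        return np.array(
            [self.sigma_OxyR, self.sigma_GrxA, self.sigma_KatG, self.sigma_AhpC]
        )

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def default_parameters(
    variant: str = "oxidative", medium: str = "glucose"
) -> ModelParameters:
    """Published parameter set for a model variant and growth medium.

    ``variant`` is "oxidative" (OxyR/H2O2 regulon, uM) or "general" (abstract
    toxin + detox enzyme, a.u.). ``medium`` selects g0: M9 glycerol 0.025/min,
    M9 glucose 0.042/min, M9 glucose + 10% LB 0.065/min. Geometry and growth
    parameters are shared between the two variants.
    """
    if medium not in G0_BY_MEDIUM:
        raise ConfigError(
            f"unknown medium {medium!r}; expected one of {sorted(G0_BY_MEDIUM)}"
        )
    if variant not in ("oxidative", "general"):
        raise ConfigError(f"unknown variant {variant!r}")
    extra = {}
    if variant == "general":
        # the growth sigmoid operates on a.u. toxin levels of order h_E = 1,
        # so its half-inhibition point and steepness live on that scale too
        extra = {"c1": 1.0, "c2": 1.0}
    return ModelParameters(
        variant=variant, medium=medium, g0=G0_BY_MEDIUM[medium], **extra
    )


@dataclass
class CellState:
    """One cell: geometry, cell-cycle progress, and intracellular species.

    Oxidative-variant species are uM; general-variant species (toxin_cell,
    enzyme) are a.u. ``h_ext_entry`` is the external stressor concentration at
    the cell's source-facing pole. ``g_current`` is the elongation rate used
    for dilution during the current step.
    """

    length: float
    added_length: float = 0.0
    OxyR_red: float = 1.0
    GrxA: float = 0.0
    KatG: float = 0.0
    AhpC: float = 0.0
    H2O2_cell: float = 0.0
    toxin_cell: float = 0.0
    enzyme: float = 0.0
    h_ext_entry: float = 0.0
    g_current: float = 0.0
    alive: bool = True

    def species_vector(self, variant: str = "oxidative") -> np.ndarray:
        if variant == "general":
            return np.array([self.toxin_cell, self.enzyme])
        return np.array(
            [self.OxyR_red, self.GrxA, self.KatG, self.AhpC, self.H2O2_cell]
        )

    def with_species(self, vec: np.ndarray, variant: str = "oxidative") -> "CellState":
        c = dataclasses.replace(self)
        if variant == "general":
            c.toxin_cell, c.enzyme = float(vec[0]), float(vec[1])
        else:
            (c.OxyR_red, c.GrxA, c.KatG, c.AhpC, c.H2O2_cell) = map(float, vec)
        return c

    def validate(self, params: ModelParameters | None = None) -> None:
        if self.length <= 0:
            raise ValueError(f"length must be > 0, got {self.length}")
        if self.added_length < 0:
            raise ValueError("added_length must be >= 0")
        for name in ("GrxA", "KatG", "AhpC", "H2O2_cell", "toxin_cell", "enzyme"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if params is not None and not (0 <= self.OxyR_red <= params.OxyR_total + 1e-12):
            raise ValueError(
                f"OxyR_red={self.OxyR_red} outside [0, {params.OxyR_total}]"
            )


@dataclass
class TrenchState:
    """Ordered cells in one trench.

    Index 0 is the outermost cell at the open end (x = 0, the stressor source);
    the last index is the mother cell at the closed end. ``h_boundary`` is the
    external stressor concentration in the feed channel at the trench mouth.
    """

    cells: list[CellState]
    h_boundary: float = 0.0
    t: float = 0.0
    pending_removal: bool = False

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellState]:
        return iter(self.cells)

    @property
    def mother(self) -> CellState:
        return self.cells[-1]

    @property
    def total_length(self) -> float:
        return sum(c.length for c in self.cells)


@dataclass
class Trace:
    """Uniformly sampled scalar time series with condition metadata."""

    t: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same shape")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("t must be uniformly spaced")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValueError("trace too short to define a sampling interval")
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return int(self.t.size)

    def crop(self, t_start: float = -np.inf, t_stop: float = np.inf) -> "Trace":
        m = (self.t >= t_start) & (self.t <= t_stop)
        return Trace(self.t[m], self.y[m], dict(self.meta))


_CONFIG_HEADER = """\
# chaostrench model parameters.
# Units: concentrations uM (oxidative) or a.u. (general); lengths um;
# time minutes; all rates per minute. Unknown keys are rejected on load.
"""


def save_config(params: ModelParameters, path) -> None:
    """Write parameters as a commented YAML file."""
    with open(path, "w") as fh:
        fh.write(_CONFIG_HEADER)
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_config(path) -> ModelParameters:
    """Load a parameter file written by :func:`save_config`; unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return ModelParameters.from_dict(data)
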