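"""Trench simulation: interaction -> response -> growth, step by step.

One simulated trench is an ordered row of cells in a dead-end microfluidic
channel. Each outer time step (default 1 min):

1. (I) the reaction-diffusion interaction model assigns every cell its local
   external stressor concentration, chaining the steady-state attenuation from
   the open end to the mother cell; with I uncoupled every cell sees the
   boundary concentration directly;
2. (S) the intracellular response model advances each cell's species using the
   elongation rate from the *previous* step (deterministic, or Euler-Maruyama
   when the noisy S* variant is selected);
3. (G) the growth model recomputes the elongation rate from the new
   intracellular stressor level (with G uncoupled the rate stays g0), then
   grows and divides cells; if the summed cell length exceeds the trench
   length the outermost cell is flagged and removed at the start of the next
   step. The mother cell (closed end) is never removed.

The boundary concentration is zero before the treatment time point and the
treatment concentration afterwards. Parallel trenches are independent runs
with rng streams spawned from one seed. This module doubles as the project's
synthetic-data generator: its output tables feed every analysis stage.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import response
from .growth import elongation_rate
from .interaction import attenuate_through_cell, screening_length
from .model_core import CellState, ConfigError, ModelParameters, Trace, TrenchState

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "TrenchResult",
    "init_trench",
    "step",
    "run",
    "bifurcation_scan",
    "sweep_general_model",
    "local_extrema",
]

_COUPLING_RE = re.compile(r"^S(\*)?((?:\+[GI])*)$")

#: default steady-state analysis window, minutes after treatment onset
STEADY_WINDOW = (700.0, 5200.0)


def parse_coupling(coupling: str) -> tuple[bool, bool, bool]:
    """Parse a coupling label like "S+G+I" or "S*+I" -> (noisy, has_G, has_I)."""
    m = _COUPLING_RE.match(coupling.replace(" ", ""))
    if not m:
        raise ConfigError(
            f"unrecognized coupling {coupling!r}; expected S[*][+G][+I] combinations"
        )
    noisy = m.group(1) == "*"
    extras = m.group(2)
    return noisy, "+G" in extras, "+I" in extras


@dataclass
class SimulationConfig:
    """User-facing knobs of one simulation run (or ensemble of trenches)."""

    duration: int = 5250  # number of outer time points
    dt: float = 1.0  # min
    t_treat: int = 50  # treatment onset time point
    h_treatment: float = 100.0  # boundary concentration from t_treat on (uM or a.u.)
    coupling: str = "S+G+I"
    n_trenches: int = 1
    L_trench: float | None = None  # overrides params.L_trench when set
    init_mode: str = "random"  # {"random", "explicit", "synchronized"}
    init_lengths: tuple | None = None  # for explicit mode
    epsilon: float = 0.0  # mother cell-cycle shift, synchronized mode
    rng_seed: int = 0
    n_sub: int = response.DEFAULT_N_SUB
    # concentration driving each cell's influx: at its source-facing pole
    # ("entry") or averaged over its length ("average")
    interaction_driver: str = "entry"

    def __post_init__(self) -> None:
        parse_coupling(self.coupling)  # raises on malformed labels
        if not 0 <= self.t_treat < self.duration:
            raise ConfigError("t_treat must lie inside [0, duration)")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.h_treatment < 0:
            raise ConfigError("h_treatment must be >= 0")
        if self.init_mode not in ("random", "explicit", "synchronized"):
            raise ConfigError(f"unknown init_mode {self.init_mode!r}")
        if self.interaction_driver not in ("entry", "average"):
            raise ConfigError(
                f"unknown interaction_driver {self.interaction_driver!r}"
            )

    @property
    def noisy(self) -> bool:
        return parse_coupling(self.coupling)[0]

    @property
    def has_G(self) -> bool:
        return parse_coupling(self.coupling)[1]

    @property
    def has_I(self) -> bool:
        return parse_coupling(self.coupling)[2]

    def replace(self, **changes) -> "SimulationConfig":
        return dc_replace(self, **changes)


def _species_names(params: ModelParameters) -> list[str]:
    if params.variant == "general":
        return ["toxin_cell", "enzyme"]
    return ["oxyR_red", "grxA", "katG", "ahpC", "h2o2_cell"]


def _stress_index(params: ModelParameters) -> int:
    """Column of the species array that drives growth inhibition."""
    return 0 if params.variant == "general" else 4


def init_trench(
    config: SimulationConfig,
    params: ModelParameters,
    rng: np.random.Generator | None = None,
) -> TrenchState:
    """Fill a trench with cells at their initial lengths and concentrations.

    random: lengths i.i.d. uniform on [L_div/2, L_div] with the adder counter
    uniform over the cycle (unsynchronised culture). synchronized: identical
    mid-cycle cells, with the mother's cell-cycle progress multiplied by
    (1 + epsilon). explicit: lengths given directly, adder counters at zero.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    L_trench = config.L_trench if config.L_trench is not None else params.L_trench
    L_div = params.L_div
    if L_trench < L_div / 2:
        raise ConfigError("trench too small to hold a single newborn cell")

    lengths: list[float] = []
    added: list[float] = []
    if config.init_mode == "explicit":
        if not config.init_lengths:
            raise ConfigError("explicit init requires init_lengths")
        lengths = [float(v) for v in config.init_lengths]
        added = [0.0] * len(lengths)
    elif config.init_mode == "synchronized":
        cell_len = L_div  # newborn-sized cells, half-way through the adder cycle
        mid_added = L_div / 2
        n = max(1, int(L_trench // cell_len))
        lengths = [cell_len] * n
        added = [mid_added] * n
        # Shift only the mother's cell-cycle progress: its length (which feeds
        # the diffusion model continuously) and adder counter scale by (1+eps).
        lengths[-1] = cell_len * (1.0 + config.epsilon)
        added[-1] = mid_added * (1.0 + config.epsilon)
    else:  # random
        total = 0.0
        while True:
            l = rng.uniform(L_div / 2, L_div)
            if total + l > L_trench and lengths:
                break
            lengths.append(l)
            # progress through the adder cycle, uniform in added length:
            # a cell born at length l - a has accumulated a in [0, L_div)
            added.append(rng.uniform(0.0, L_div * (l - L_div / 2) / (L_div / 2)))
            total += l
            if total > L_trench:
                break

    y0 = response.unstressed_steady_state(params)
    # with G uncoupled the elongation rate is pinned at g0 from the start
    if parse_coupling(config.coupling)[1]:
        g0_eff = float(elongation_rate(y0[_stress_index(params)], params))
    else:
        g0_eff = params.g0
    cells = []
    for l, a in zip(lengths, added):
        c = CellState(length=l, added_length=a, g_current=g0_eff)
        c = c.with_species(y0, params.variant)
        c.g_current = g0_eff
        cells.append(c)
    if sum(lengths) > L_trench + L_div:
        raise ConfigError("initial cells do not fit in the trench")
    return TrenchState(cells=cells, h_boundary=0.0, t=0.0)


# ---------------------------------------------------------------------------
# array-based stepping (single code path used by both `step` and `run`)


class _ArrayTrench:
    """Mutable array representation of one trench (fast inner loop)."""

    __slots__ = (
        "lengths", "added", "Y", "h_entry", "g", "ids", "parent",
        "next_id", "h_boundary", "t", "pending_removal",
    )

    def __init__(self, trench: TrenchState, params: ModelParameters):
        n = len(trench.cells)
        self.lengths = np.array([c.length for c in trench.cells])
        self.added = np.array([c.added_length for c in trench.cells])
        self.Y = np.stack(
            [c.species_vector(params.variant) for c in trench.cells]
        ).astype(float)
        self.h_entry = np.array([c.h_ext_entry for c in trench.cells])
        self.g = np.array([c.g_current for c in trench.cells])
        self.ids = np.arange(n, dtype=np.int64)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.next_id = n
        self.h_boundary = trench.h_boundary
        self.t = trench.t
        self.pending_removal = trench.pending_removal

    @property
    def n(self) -> int:
        return self.lengths.size

    def to_state(self, params: ModelParameters) -> TrenchState:
        cells = []
        for i in range(self.n):
            c = CellState(
                length=float(self.lengths[i]),
                added_length=float(self.added[i]),
                h_ext_entry=float(self.h_entry[i]),
                g_current=float(self.g[i]),
            )
            cells.append(c.with_species(self.Y[i], params.variant))
        return TrenchState(
            cells=cells,
            h_boundary=self.h_boundary,
            t=self.t,
            pending_removal=self.pending_removal,
        )


def _step_arrays(
    tr: _ArrayTrench,
    config: SimulationConfig,
    params: ModelParameters,
    noise: response.NoiseConfig | None,
) -> bool:
    """Advance one outer step in place; returns True if the mother divided."""
    noisy, has_G, has_I = parse_coupling(config.coupling)
    L_trench = config.L_trench if config.L_trench is not None else params.L_trench

    # deferred removal of the outermost cell (never the mother)
    if tr.pending_removal and tr.n > 1:
        for name in ("lengths", "added", "h_entry", "g", "ids", "parent"):
            setattr(tr, name, getattr(tr, name)[1:])
        tr.Y = tr.Y[1:]
    tr.pending_removal = False

    # (I) external stressor profile
    if has_I:
        h = tr.h_boundary
        average = config.interaction_driver == "average"
        for i in range(tr.n):
            l = float(tr.lengths[i])
            if average:
                lam = screening_length(l, params)
                # spatial mean of the cosh profile over the cell's length
                tr.h_entry[i] = (
                    h if math.isinf(lam) else h * (lam / l) * math.tanh(l / lam)
                )
            else:
                tr.h_entry[i] = h
            _, h = attenuate_through_cell(h, l, params)
    else:
        tr.h_entry[:] = tr.h_boundary

    # (S) intracellular response, using last step's g
    if noisy:
        response.stochastic_step_cells(
            tr.Y, tr.h_entry, tr.g, params, config.dt, noise
        )
    else:
        response.integrate_cells(
            tr.Y, tr.h_entry, tr.g, params, config.dt, config.n_sub
        )

    # (G) growth, division, overflow bookkeeping
    if has_G:
        g_new = elongation_rate(tr.Y[:, _stress_index(params)], params)
        g_new = np.atleast_1d(g_new)
    else:
        g_new = np.full(tr.n, params.g0)
    increment = tr.lengths * g_new
    tr.lengths = tr.lengths + increment
    tr.added = tr.added + increment
    tr.g = g_new

    mother_divided = False
    dividing = np.flatnonzero(tr.added > params.L_div)
    if dividing.size:
        mother_divided = dividing[-1] == tr.n - 1
        for i in dividing[::-1]:  # back-to-front keeps earlier indices valid
            half = tr.lengths[i] / 2.0
            tr.lengths = np.insert(tr.lengths, i, half)
            tr.lengths[i + 1] = half
            tr.added = np.insert(tr.added, i, 0.0)
            tr.added[i + 1] = 0.0
            tr.Y = np.insert(tr.Y, i, tr.Y[i], axis=0)
            tr.h_entry = np.insert(tr.h_entry, i, tr.h_entry[i])
            tr.g = np.insert(tr.g, i, tr.g[i])
            pid = tr.ids[i]
            tr.parent = np.insert(tr.parent, i, pid)
            tr.parent[i + 1] = pid
            tr.ids = np.insert(tr.ids, i, tr.next_id)
            tr.ids[i + 1] = tr.next_id + 1
            tr.next_id += 2

    tr.pending_removal = bool(tr.lengths.sum() > L_trench)
    tr.t += config.dt
    return mother_divided


def step(
    trench: TrenchState,
    config: SimulationConfig,
    params: ModelParameters,
    noise: response.NoiseConfig | None = None,
) -> TrenchState:
    """Advance a trench by one outer time step (functional wrapper)."""
    if len(trench.cells) == 0:
        raise ValueError("trench has no cells")
    if config.noisy and noise is None:
        noise = response.NoiseConfig.from_params(params, rng_seed=config.rng_seed)
    tr = _ArrayTrench(trench, params)
    _step_arrays(tr, config, params, noise)
    return tr.to_state(params)


@dataclass
class TrenchResult:
    """Per-step records of one simulated trench."""

    params: ModelParameters
    config: SimulationConfig
    trench_id: int
    times: np.ndarray  # (T,)
    n_cells: np.ndarray  # (T,)
    ids: list  # T arrays of cell ids (open end first)
    parents: list
    lengths: list
    species: list  # T arrays (n_t, n_species)
    h_entry: list
    g: list
    mother_division: np.ndarray  # (T,) bool

    @property
    def species_names(self) -> list[str]:
        return _species_names(self.params)

    def mother_trace(self, species: str = "grxA") -> Trace:
        names = self.species_names
        if species in names:
            j = names.index(species)
            y = np.array([s[-1, j] for s in self.species])
        elif species == "g":
            y = np.array([gi[-1] for gi in self.g])
        elif species == "length":
            y = np.array([li[-1] for li in self.lengths])
        elif species == "h_ext_entry":
            y = np.array([hi[-1] for hi in self.h_entry])
        else:
            raise KeyError(f"unknown mother-cell series {species!r}")
        meta = {
            "trench_id": self.trench_id,
            "species": species,
            "h_treatment": self.config.h_treatment,
            "coupling": self.config.coupling,
            "role": "mother",
        }
        return Trace(self.times, y, meta)

    def cell_count_trace(self) -> Trace:
        return Trace(
            self.times,
            self.n_cells.astype(float),
            {"trench_id": self.trench_id, "species": "n_cells"},
        )

    def steady_window_times(self) -> tuple[float, float]:
        t0 = self.config.t_treat * self.config.dt
        return t0 + STEADY_WINDOW[0], t0 + STEADY_WINDOW[1]

    def mother_steady_trace(self, species: str = "grxA") -> Trace:
        lo, hi = self.steady_window_times()
        return self.mother_trace(species).crop(lo, hi)

    def mother_interdivision_times(self, t_min: float = 0.0) -> np.ndarray:
        """Intervals (min) between consecutive mother-cell divisions."""
        t_div = self.times[self.mother_division & (self.times >= t_min)]
        return np.diff(t_div)

    def mean_g_by_position(
        self, t_start: float, t_stop: float = np.inf
    ) -> pd.Series:
        """Time-averaged elongation rate per trench position (0 = open end)."""
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for t, garr in zip(self.times, self.g):
            if t_start <= t <= t_stop:
                for pos, gval in enumerate(garr):
                    sums[pos] = sums.get(pos, 0.0) + float(gval)
                    counts[pos] = counts.get(pos, 0) + 1
        pos = sorted(sums)
        return pd.Series(
            [sums[p] / counts[p] for p in pos], index=pd.Index(pos, name="position")
        )

    def mean_species_at_position(
        self, species: str, position: int, t_start: float, t_stop: float = np.inf
    ) -> float:
        j = self.species_names.index(species)
        vals = [
            s[position, j]
            for t, s in zip(self.times, self.species)
            if t_start <= t <= t_stop and s.shape[0] > position
        ]
        if not vals:
            raise ValueError("no records at the requested position/window")
        return float(np.mean(vals))

    def to_table(self) -> pd.DataFrame:
        """Tidy per-cell per-time table (the simulator's export schema)."""
        rows = {
            "trench_id": [], "cell_id": [], "parent_id": [], "position_index": [],
            "time_min": [], "length_um": [],
        }
        names = self.species_names
        for nm in names:
            rows[nm] = []
        rows["stress_ext_entry"] = []
        rows["g"] = []
        rows["n_cells_in_trench"] = []
        for k, t in enumerate(self.times):
            n = len(self.ids[k])
            rows["trench_id"].extend([self.trench_id] * n)
            rows["cell_id"].extend(self.ids[k].tolist())
            rows["parent_id"].extend(self.parents[k].tolist())
            rows["position_index"].extend(range(n))
            rows["time_min"].extend([float(t)] * n)
            rows["length_um"].extend(self.lengths[k].tolist())
            for j, nm in enumerate(names):
                rows[nm].extend(self.species[k][:, j].tolist())
            rows["stress_ext_entry"].extend(self.h_entry[k].tolist())
            rows["g"].extend(self.g[k].tolist())
            rows["n_cells_in_trench"].extend([n] * n)
        return pd.DataFrame(rows)


@dataclass
class SimulationResult:
    """Ensemble of independent trench runs under one configuration."""

    params: ModelParameters
    config: SimulationConfig
    trenches: list[TrenchResult] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trenches)

    def __getitem__(self, i: int) -> TrenchResult:
        return self.trenches[i]

    def mother_traces(self, species: str = "grxA") -> list[Trace]:
        return [tr.mother_trace(species) for tr in self.trenches]

    def to_table(self) -> pd.DataFrame:
        return pd.concat([tr.to_table() for tr in self.trenches], ignore_index=True)


def run_single(
    config: SimulationConfig,
    params: ModelParameters,
    seed=None,
    trench_id: int = 0,
) -> TrenchResult:
    """Run one trench for ``config.duration`` time points."""
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    noise = None
    if config.noisy:
        noise = response.NoiseConfig.from_params(params)
        noise._rng = rng
    trench = init_trench(config, params, rng=rng)
    tr = _ArrayTrench(trench, params)

    times = np.arange(config.duration, dtype=float) * config.dt
    n_cells = np.zeros(config.duration, dtype=np.int64)
    mother_division = np.zeros(config.duration, dtype=bool)
    ids, parents, lengths, species, h_entry, g = [], [], [], [], [], []
    for i in range(config.duration):
        tr.h_boundary = config.h_treatment if i >= config.t_treat else 0.0
        mother_division[i] = _step_arrays(tr, config, params, noise)
        n_cells[i] = tr.n
        ids.append(tr.ids.copy())
        parents.append(tr.parent.copy())
        lengths.append(tr.lengths.copy())
        species.append(tr.Y.copy())
        h_entry.append(tr.h_entry.copy())
        g.append(tr.g.copy())
        if not np.all(np.isfinite(tr.Y)):
            raise ArithmeticError(
                f"non-finite state at time point {i} in trench {trench_id}"
            )
    return TrenchResult(
        params=params, config=config, trench_id=trench_id, times=times,
        n_cells=n_cells, ids=ids, parents=parents, lengths=lengths,
        species=species, h_entry=h_entry, g=g, mother_division=mother_division,
    )


def run(config: SimulationConfig, params: ModelParameters) -> SimulationResult:
    """Run ``config.n_trenches`` independent trenches (spawned rng streams)."""
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_trenches)
    result = SimulationResult(params=params, config=config)
    for k, s in enumerate(seeds):
        result.trenches.append(run_single(config, params, seed=s, trench_id=k))
    return result


def local_extrema(y: np.ndarray) -> np.ndarray:
    """Values of strict local maxima and minima of a series."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        return np.empty(0)
    interior = y[1:-1]
    maxima = (interior > y[:-2]) & (interior > y[2:])
    minima = (interior < y[:-2]) & (interior < y[2:])
    return interior[maxima | minima]


def bifurcation_scan(
    concentrations,
    config: SimulationConfig,
    params: ModelParameters,
    species: str = "grxA",
) -> pd.DataFrame:
    """Extrema of the mother-cell trace per boundary concentration.

    Runs ``config.n_trenches`` replicates per concentration and extracts all
    local extrema of the mother trace over the steady-state window; the
    (concentration, extrema) pairs form the bifurcation diagram and the
    per-replicate extrema counts the regime histograms.
    """
    rows = []
    for conc in concentrations:
        if conc < 0:
            raise ConfigError("concentrations must be >= 0")
        res = run(config.replace(h_treatment=float(conc)), params)
        for tr in res.trenches:
            trace = tr.mother_steady_trace(species)
            if len(trace) < 3:
                raise ConfigError("steady-state window lies outside the run")
            ext = local_extrema(trace.y)
            rows.append(
                {
                    "concentration": float(conc),
                    "trench_id": tr.trench_id,
                    "extrema": ext,
                    "n_extrema": int(ext.size),
                }
            )
    return pd.DataFrame(rows)


def sweep_general_model(
    axis: str,
    values,
    config: SimulationConfig,
    params: ModelParameters,
) -> pd.DataFrame:
    """Lyapunov exponent of mother-cell enzyme dynamics along a parameter axis.

    ``axis`` is one of "toxin_ext" (the boundary concentration), "K_cat", or
    "K_act". Returns one row per (value, replicate) with the Lyapunov estimate
    of the steady-state enzyme trace.
    """
    from .metrics import lyapunov_exponent

    if params.variant != "general":
        raise ConfigError(
            "sweep_general_model requires general-variant parameters "
            "(default_parameters('general'))"
        )
    if axis not in ("toxin_ext", "K_cat", "K_act"):
        raise ConfigError(f"unknown sweep axis {axis!r}")
    rows = []
    for v in values:
        p, c = params, config
        if axis == "toxin_ext":
            c = config.replace(h_treatment=float(v))
        else:
            p = params.replace(**{axis: float(v)})
        res = run(c, p)
        for tr in res.trenches:
            trace = tr.mother_steady_trace("enzyme")
            if np.std(trace.y) < 1e-12:
                lam = 0.0  # flat dynamics: no divergence to measure
            else:
                lam = lyapunov_exponent(trace)
            rows.append({"axis": axis, "value": float(v),
                         "trench_id": tr.trench_id, "lyapunov": float(lam)})
    return pd.DataFrame(rows)
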