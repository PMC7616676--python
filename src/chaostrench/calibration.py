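"""Grid-search calibration fits against measured summaries.

Two mean-absolute-error (MAE) fits tie the model to mother-machine data:

* ``fit_c1`` - the steepness of the growth-inhibition sigmoid, fitted so that
  simulated steady-state elongation rates across trench positions and H2O2
  concentrations match observed ones (the published optimum is 2e4 / uM,
  scanned over five orders of magnitude from 200 / uM);
* ``fit_reporter_scale`` - the linear factor converting model GrxA
  concentration to reporter fluorescence intensity, fitted on open-end cells
  (grid 0..2500 in steps of 50; published optimum 1150).

MAE here is the mean of absolute *relative* errors, matching the printed
formula. "Steady state" is the time average over the final 20% of the run.
Both fits are exact-recovery consistent: data generated by the forward model
at a grid value are recovered at that value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import ModelParameters
from .simulator import SimulationConfig, run_single

__all__ = [
    "PAPER_CONCENTRATIONS",
    "C1_GRID",
    "REPORTER_GRID",
    "model_growth_by_position",
    "model_reporter_at_open_end",
    "fit_c1",
    "fit_reporter_scale",
]

#: H2O2 panel used for both calibration fits (uM)
PAPER_CONCENTRATIONS = (12.5, 25.0, 37.5, 50.0, 62.5, 75.0, 82.5, 100.0, 500.0)

#: default c1 grid: five orders of magnitude from 200 / uM
C1_GRID = tuple(np.logspace(np.log10(200.0), np.log10(2e7), 26))

#: default reporter-scale grid: 0 to 2500, step 50
REPORTER_GRID = tuple(np.arange(0, 2501, 50, dtype=float))

_STEADY_FRACTION = 0.8  # average over the final 20% of the run


def _steady_start(config: SimulationConfig) -> float:
    return _STEADY_FRACTION * config.duration * config.dt


def model_growth_by_position(
    config: SimulationConfig,
    params: ModelParameters,
    conditions=PAPER_CONCENTRATIONS,
) -> pd.DataFrame:
    """Steady-state elongation rate per (H2O2 condition, trench position).

    Forward model used inside :func:`fit_c1`; also convenient for generating
    self-consistent observations in tests.
    """
    rows = []
    t0 = _steady_start(config)
    for conc in conditions:
        res = run_single(config.replace(h_treatment=float(conc)), params)
        g_by_pos = res.mean_g_by_position(t_start=t0)
        for pos, gval in g_by_pos.items():
            rows.append({"h2o2": float(conc), "position": int(pos), "g": gval})
    return pd.DataFrame(rows)


def model_reporter_at_open_end(
    config: SimulationConfig,
    params: ModelParameters,
    conditions=PAPER_CONCENTRATIONS,
) -> pd.DataFrame:
    """Steady-state open-end (position 0) GrxA concentration per condition."""
    rows = []
    t0 = _steady_start(config)
    for conc in conditions:
        res = run_single(config.replace(h_treatment=float(conc)), params)
        val = res.mean_species_at_position("grxA", 0, t_start=t0)
        rows.append({"h2o2": float(conc), "grxA_model": val})
    return pd.DataFrame(rows)


def _relative_mae(observed: np.ndarray, model: np.ndarray) -> float:
    denom = np.maximum(np.abs(observed), 1e-12)
    return float(np.mean(np.abs(model - observed) / denom))


def fit_c1(
    observed: pd.DataFrame,
    grid=C1_GRID,
    config: SimulationConfig | None = None,
    params: ModelParameters | None = None,
):
    """MAE grid search for the growth-inhibition steepness c1.

    ``observed`` must have columns ``h2o2``, ``position``, ``g`` (steady-state
    elongation rates). For each grid value the full model is simulated at each
    observed H2O2 condition and the mean absolute relative error across all
    (condition, position) pairs is accumulated. Returns
    ``(best_c1, curve)`` where ``curve`` is a DataFrame of (c1, mae).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty c1 grid")
    for col in ("h2o2", "position", "g"):
        if col not in observed.columns:
            raise ValueError(f"observed table missing column {col!r}")
    config = config or SimulationConfig()
    params = params or ModelParameters()
    conditions = sorted(observed["h2o2"].unique())

    maes = []
    for c1 in grid:
        model = model_growth_by_position(
            config, params.replace(c1=float(c1)), conditions
        )
        # inner join: positions the trench does not reach at this c1 (cell
        # counts vary with growth inhibition) simply contribute no pairs
        merged = observed.merge(
            model, on=["h2o2", "position"], how="inner", suffixes=("_obs", "_model")
        )
        if merged.empty or len(merged) < len(observed) / 2:
            raise ValueError(
                "observed conditions/positions outside the simulated range "
                f"(matched {len(merged)}/{len(observed)} pairs at c1={c1:g})"
            )
        maes.append(_relative_mae(merged["g_obs"].to_numpy(),
                                  merged["g_model"].to_numpy()))
    curve = pd.DataFrame({"c1": grid, "mae": maes})
    best = float(curve.loc[curve["mae"].idxmin(), "c1"])
    return best, curve


def fit_reporter_scale(
    observed: pd.DataFrame,
    grid=REPORTER_GRID,
    config: SimulationConfig | None = None,
    params: ModelParameters | None = None,
):
    """MAE grid search for the GrxA-to-reporter intensity scale factor.

    ``observed`` must have columns ``h2o2`` and ``intensity`` (steady-state
    reporter level of the open-end cell per condition). The model's open-end
    GrxA is computed once; the scale is a linear grid search. Returns
    ``(best_scale, curve)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty scale grid")
    for col in ("h2o2", "intensity"):
        if col not in observed.columns:
            raise ValueError(f"observed table missing column {col!r}")
    config = config or SimulationConfig()
    params = params or ModelParameters()
    conditions = sorted(observed["h2o2"].unique())
    model = model_reporter_at_open_end(config, params, conditions)
    merged = observed.merge(model, on="h2o2", how="left")
    if merged["grxA_model"].isna().any():
        raise ValueError("observed conditions outside the simulated range")
    obs = merged["intensity"].to_numpy(dtype=float)
    mod = merged["grxA_model"].to_numpy(dtype=float)
    maes = [_relative_mae(obs, k * mod) for k in grid]
    curve = pd.DataFrame({"k": grid, "mae": maes})
    best = float(curve.loc[curve["mae"].idxmin(), "k"])
    return best, curve
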