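"""Trace tables, fixture generation, and surrogates.

The exchange format is a tidy comma-separated table with one row per cell per
frame (the same schema the simulator exports and the analysis CLI reads for
experimental-style data). Fixture traces with known dynamics - sine, logistic
map, white noise, AR(1), constant - exercise every chaos metric without any
simulation run or external file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import Trace

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_trace_table",
    "write_trace_table",
    "validate_trace_table",
    "mother_trace_from_table",
    "make_fixture",
    "make_surrogate",
]

REQUIRED_COLUMNS = (
    "trench_id",
    "cell_id",
    "parent_id",
    "position_index",
    "time_min",
    "length_um",
    "n_cells_in_trench",
)


class SchemaError(ValueError):
    """A trace table violates the documented schema."""


def validate_trace_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trace table missing required columns: {missing}")
    extra = [c for c in table.columns if c not in REQUIRED_COLUMNS]
    if not extra:
        raise SchemaError(
            "trace table has no reporter/species columns beyond the schema core"
        )
    # per (trench, cell) time must be strictly increasing and uniform
    for (tid, cid), grp in table.groupby(["trench_id", "cell_id"]):
        t = grp["time_min"].to_numpy(dtype=float)
        if t.size >= 2:
            d = np.diff(t)
            if np.any(d <= 0):
                raise SchemaError(
                    f"time not strictly increasing for trench {tid} cell {cid}"
                )
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
                raise SchemaError(
                    f"time not uniformly sampled for trench {tid} cell {cid}"
                )
    return table


def write_trace_table(table: pd.DataFrame, path) -> None:
    validate_trace_table(table)
    table.to_csv(path, index=False)


def read_trace_table(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # unparseable input -> explicit error
        raise SchemaError(f"could not parse trace table {path}: {exc}") from exc
    return validate_trace_table(table)


def mother_trace_from_table(
    table: pd.DataFrame, trench_id, column: str
) -> Trace:
    """Mother-cell series: the highest position index at every frame."""
    sub = table[table["trench_id"] == trench_id]
    if sub.empty:
        raise SchemaError(f"no rows for trench {trench_id!r}")
    if column not in sub.columns:
        raise SchemaError(f"no column {column!r} in trace table")
    mothers = sub.loc[sub.groupby("time_min")["position_index"].idxmax()]
    mothers = mothers.sort_values("time_min")
    return Trace(
        mothers["time_min"].to_numpy(dtype=float),
        mothers[column].to_numpy(dtype=float),
        {"trench_id": trench_id, "species": column, "role": "mother"},
    )


def make_fixture(kind: str, n: int, seed=None, **kw) -> Trace:
    """Reproducible trace with known dynamics for metric regression tests.

    kinds: ``sine`` (period, amplitude, phase, dt), ``logistic_map`` (r, x0),
    ``white_noise`` (mean, sd), ``ar1`` (phi, mean, sd - the *stationary*
    moments; innovations are scaled by sqrt(1 - phi^2)), ``constant`` (value).
    Generative parameters are stored in ``meta``.
    """
    if n < 10:
        raise ValueError("fixture length must be >= 10")
    rng = np.random.default_rng(seed)
    dt = float(kw.pop("dt", 1.0))
    t = np.arange(n, dtype=float) * dt
    meta = {"kind": kind, "seed": seed, "dt": dt}

    if kind == "sine":
        period = float(kw.pop("period", 60.0))
        amplitude = float(kw.pop("amplitude", 1.0))
        phase = float(kw.pop("phase", 0.0))
        y = amplitude * np.sin(2 * np.pi * t / period + phase)
        meta.update(period=period, amplitude=amplitude, phase=phase)
    elif kind == "logistic_map":
        r = float(kw.pop("r", 4.0))
        x0 = kw.pop("x0", None)
        x = float(rng.uniform(0.05, 0.95)) if x0 is None else float(x0)
        y = np.empty(n)
        for i in range(n):
            y[i] = x
            x = r * x * (1.0 - x)
        meta.update(r=r, x0=y[0])
    elif kind == "white_noise":
        mean = float(kw.pop("mean", 0.0))
        sd = float(kw.pop("sd", 1.0))
        y = rng.normal(mean, sd, size=n)
        meta.update(mean=mean, sd=sd)
    elif kind == "ar1":
        phi = float(kw.pop("phi", 0.9))
        mean = float(kw.pop("mean", 0.0))
        sd = float(kw.pop("sd", 1.0))
        if not -1 < phi < 1:
            raise ValueError("AR(1) requires |phi| < 1 for stationarity")
        innov_sd = sd * np.sqrt(1.0 - phi * phi)
        y = np.empty(n)
        x = rng.normal(0.0, sd)  # start in the stationary distribution
        for i in range(n):
            y[i] = x
            x = phi * x + rng.normal(0.0, innov_sd)
        y += mean
        meta.update(phi=phi, mean=mean, sd=sd)
    elif kind == "constant":
        value = float(kw.pop("value", 1.0))
        y = np.full(n, value)
        meta.update(value=value)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if kw:
        raise TypeError(f"unknown fixture parameters: {sorted(kw)}")
    return Trace(t, y, meta)


def make_surrogate(trace: Trace, kind: str = "shuffle", seed=None) -> Trace:
    """Value-preserving random permutation: destroys temporal order, keeps
    the value multiset (hence mean and standard deviation) exactly."""
    if kind != "shuffle":
        raise ValueError(f"unknown surrogate kind {kind!r}")
    if len(trace) < 2:
        raise ValueError("need at least 2 points to shuffle")
    rng = np.random.default_rng(seed)
    meta = dict(trace.meta)
    meta["surrogate"] = kind
    return Trace(trace.t.copy(), rng.permutation(trace.y), meta)
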