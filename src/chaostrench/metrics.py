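"""Chaos-detection toolkit for single-cell reporter traces.

Implements the quantification battery used on both simulated and
experimental-style traces: largest Lyapunov exponent (Rosenstein
mean-divergence method on a time-delay embedding), Grassberger-Procaccia
correlation dimension with embedding-dimension saturation, autocorrelation
periodicity (on the frame-difference signal, with peak prominence 0.2),
permutation-entropy determinism test against shuffled surrogates, a windowed
stationarity check, dead-cell classification, and lagged cross-correlation.

Sign conventions: Lyapunov > 0 marks chaos; a correlation dimension that
saturates with embedding dimension marks determinism, while D_corr ~ E marks
noise; permutation entropy below the shuffled-surrogate distribution marks
determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist
from statsmodels.tsa.stattools import acf as sm_acf

from .model_core import Trace

__all__ = [
    "ChaosReport",
    "preprocess_trace",
    "difference_signal",
    "acf_with_peaks",
    "mean_acf",
    "lyapunov_exponent",
    "correlation_dimension",
    "CorrelationDimensionResult",
    "permutation_entropy",
    "determinism_test",
    "stationarity_test",
    "classify_alive",
    "cross_correlation",
    "analyze_trace",
    "DEAD_GROWTH_THRESHOLD",
]

#: a mother cell is dead when its mean length growth rate falls below this (1/min)
DEAD_GROWTH_THRESHOLD = 0.0024


def _as_trace(trace) -> Trace:
    if isinstance(trace, Trace):
        return trace
    y = np.asarray(trace, dtype=float)
    return Trace(np.arange(y.size, dtype=float), y)


def preprocess_trace(
    trace, window: int = 3, passes: int = 2, t_start: float = -np.inf
) -> Trace:
    """Crop to t >= t_start and apply a centred moving-mean ``passes`` times.

    The window shrinks at the trace edges (no padding, no fabricated samples).
    ``passes=0`` or ``window=1`` crops only. Simulated traces are analysed
    unsmoothed; experimental-style reporter traces use window 3 (or 6 for slow
    growth media), applied twice.
    """
    tr = _as_trace(trace).crop(t_start=t_start)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(tr) < max(window, 3):
        raise ValueError(
            f"trace too short for analysis: {len(tr)} points after cropping"
        )
    y = tr.y
    for _ in range(passes if window > 1 else 0):
        y = (
            pd.Series(y)
            .rolling(window=window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return Trace(tr.t, y, dict(tr.meta))


def difference_signal(trace) -> Trace:
    """Frame-to-frame difference y[i+1] - y[i]; removes slow trends."""
    tr = _as_trace(trace)
    if len(tr) < 2:
        raise ValueError("need at least 2 points to difference")
    return Trace(tr.t[1:], np.diff(tr.y), dict(tr.meta))


def acf_with_peaks(trace, max_lag: int | None = None, prominence: float = 0.2):
    """Autocorrelation values and prominent peak lags of one trace.

    Returns ``(acf_values, peak_lags, period)`` where ``acf_values[k]`` is the
    standard biased autocorrelation at lag k (ACF(0) = 1), ``peak_lags`` are
    the lags (in samples) of peaks with the given prominence, and ``period``
    is the first peak lag converted to time units (None when no peak).
    """
    tr = _as_trace(trace)
    if np.std(tr.y) == 0:
        raise ValueError("zero-variance trace has no autocorrelation structure")
    n = len(tr)
    if max_lag is None:
        max_lag = min(n - 2, n // 2)
    vals = sm_acf(tr.y, nlags=max_lag, fft=True)
    peak_idx, _ = find_peaks(vals, prominence=prominence)
    dt = tr.dt if n >= 2 else 1.0
    period = float(peak_idx[0] * dt) if peak_idx.size else None
    return vals, peak_idx, period


def mean_acf(traces, max_lag: int, prominence: float = 0.2):
    """Average single-trace ACFs lag-by-lag, then find prominent peaks."""
    curves = []
    for tr in traces:
        vals, _, _ = acf_with_peaks(tr, max_lag=max_lag, prominence=np.inf)
        curves.append(vals)
    mean_curve = np.mean(np.vstack(curves), axis=0)
    peak_idx, _ = find_peaks(mean_curve, prominence=prominence)
    return mean_curve, peak_idx


def _delay_embedding(y: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n_vec = y.size - (dim - 1) * delay
    if n_vec < 2:
        raise ValueError("trace too short for the requested embedding")
    return sliding_window_view(y, (dim - 1) * delay + 1)[:, ::delay]


def _acf_decay_lag(y: np.ndarray, max_lag: int | None = None) -> int:
    """First lag where the ACF drops below 1/e (standard embedding delay)."""
    max_lag = max_lag or min(y.size // 4, 500)
    vals = sm_acf(y, nlags=max_lag, fft=True)
    below = np.flatnonzero(vals < 1.0 / math.e)
    return int(below[0]) if below.size else max_lag


def _dominant_period(y: np.ndarray) -> int:
    """Mean oscillation period (samples) from the dominant FFT component."""
    yc = y - y.mean()
    spec = np.abs(np.fft.rfft(yc)) ** 2
    if spec.size < 3:
        return 1
    k = int(np.argmax(spec[1:]) + 1)
    return max(1, int(round(y.size / k)))


def lyapunov_exponent(
    trace,
    dim: int = 3,
    delay: int | None = None,
    theiler: int | None = None,
    k_max: int | None = None,
    min_length: int = 500,
) -> float:
    """Largest Lyapunov exponent by the Rosenstein mean-divergence method.

    The trace is z-scored, embedded with time-delay ``delay`` (default: the
    first ACF 1/e-crossing) in ``dim`` dimensions; each point is paired with
    its nearest neighbour outside a Theiler window (default: the dominant
    oscillation period), and the slope of the mean log divergence over the
    initial linear region, per unit time, is returned. Positive values mark
    chaos; periodic or fixed dynamics give values <= 0 (up to estimator
    noise).
    """
    tr = _as_trace(trace)
    y = tr.y
    if y.size < min_length:
        raise ValueError(f"trace too short for Lyapunov estimation: {y.size}")
    sd = y.std()
    if sd == 0:
        raise ValueError("constant trace has no divergence to measure")
    y = (y - y.mean()) / sd
    dt = tr.dt

    if delay is None:
        delay = max(1, _acf_decay_lag(y))
    emb = _delay_embedding(y, dim, delay)
    m = emb.shape[0]
    if theiler is None:
        theiler = min(max(_dominant_period(y), (dim - 1) * delay), m // 20 + 1)
    if k_max is None:
        k_max = min(max(100, 4 * _dominant_period(y)), m // 4)

    usable = m - k_max
    if usable <= theiler + 2:
        raise ValueError("trace too short for the divergence horizon")
    # nearest neighbour for each usable point, excluding a temporal band
    dists = cdist(emb[:usable], emb[:usable]).astype(np.float64)
    idx = np.arange(usable)
    band = np.abs(idx[:, None] - idx[None, :]) <= theiler
    dists[band] = np.inf
    nn = np.argmin(dists, axis=1)
    finite = np.isfinite(dists[idx, nn])
    i_idx, j_idx = idx[finite], nn[finite]

    eps = 1e-12
    curve = np.empty(k_max + 1)
    for k in range(k_max + 1):
        sep = emb[i_idx + k] - emb[j_idx + k]
        d = np.sqrt((sep * sep).sum(axis=1))
        curve[k] = np.mean(np.log(np.maximum(d, eps)))

    plateau = float(curve.max())
    rise = plateau - curve[0]
    if rise > 0.1:
        # initial linear region: up to 50% of the total rise
        cutoff = curve[0] + 0.5 * rise
        k_fit = int(np.argmax(curve >= cutoff))
        k_fit = max(k_fit, 3)
    else:
        k_fit = k_max  # no divergence: slope over the whole horizon (~0)
    ks = np.arange(k_fit + 1)
    slope = np.polyfit(ks, curve[: k_fit + 1], 1)[0]
    return float(slope / dt)


@dataclass
class CorrelationDimensionResult:
    """Correlation dimension vs embedding dimension, with saturation summary."""

    embedding_dims: np.ndarray
    d_corr: np.ndarray
    saturated: bool
    saturation: float  # plateau estimate (mean over the last dimensions)
    curves: pd.DataFrame = field(repr=False)  # per-(E, r): C(E, r)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"E": self.embedding_dims, "D_corr": self.d_corr})


def correlation_dimension(
    trace,
    e_range=range(1, 9),
    n_radii: int = 30,
    theiler: int | None = None,
    exclude_adjacent: bool = True,
    min_length: int = 200,
    saturation_step: float = 0.25,
) -> CorrelationDimensionResult:
    """Grassberger-Procaccia correlation dimension over embedding dimensions.

    For each embedding dimension E the correlation sum C(E, r) (fraction of
    delay-vector pairs within distance r, Chebyshev norm) is evaluated on
    radii log-spaced from 0.01 sigma to 3 sigma of the trace, and D_corr(E) is
    the slope of log C vs log r over the small-r scaling region
    (1e-3 <= C <= 1e-1, widened if fewer than 5 radii qualify). Temporally
    adjacent pairs are excluded by default (Theiler guard, |i-j| <= embedding
    window); set ``exclude_adjacent=False`` to sum all pairs. The curve
    saturates (plateaus) for deterministic dynamics and tracks D_corr ~ E for
    noise; ``saturation`` averages D_corr over the last three dimensions and
    ``saturated`` says whether the final increments stay below
    ``saturation_step`` per dimension.
    """
    tr = _as_trace(trace)
    y = tr.y.astype(np.float64)
    n = y.size
    if n < min_length:
        raise ValueError(f"trace too short for correlation dimension: {n}")
    sigma = y.std()
    if sigma == 0:
        raise ValueError("constant trace has no correlation structure")
    e_range = np.asarray(list(e_range), dtype=int)
    e_max = int(e_range.max())
    radii = np.logspace(np.log10(0.01 * sigma), np.log10(3 * sigma), n_radii)

    m = n - e_max + 1  # common vector count so distances grow incrementally
    t_gap = (theiler if theiler is not None else e_max) if exclude_adjacent else 0

    # incremental Chebyshev distances: D_E+1 = max(D_E, |y[i+E] - y[j+E]|)
    block = 512
    d_cheb = np.zeros((m, m), dtype=np.float32)
    counts = {}
    edges = np.concatenate([[0.0], radii])
    col = np.arange(m)
    e_done = 0
    for e in range(1, e_max + 1):
        ye = y[e - 1 : e - 1 + m].astype(np.float32)
        for s in range(0, m, block):
            stop = min(s + block, m)
            np.maximum(
                d_cheb[s:stop],
                np.abs(ye[s:stop, None] - ye[None, :]),
                out=d_cheb[s:stop],
            )
        e_done = e
        if e in e_range:
            hist = np.zeros(n_radii, dtype=np.int64)
            n_pairs = 0
            for s in range(0, m, block):
                stop = min(s + block, m)
                mask = col[None, :] > (col[s:stop, None] + t_gap)
                vals = d_cheb[s:stop][mask]
                hist += np.histogram(vals, bins=edges)[0]
                n_pairs += vals.size
            c_of_r = np.cumsum(hist) / max(n_pairs, 1)
            counts[e] = c_of_r

    rows, d_vals = [], []
    for e in e_range:
        c_of_r = counts[int(e)]
        d_vals.append(_scaling_slope(radii, c_of_r))
        for r, c in zip(radii, c_of_r):
            rows.append({"E": int(e), "r": float(r), "C": float(c)})
    d_vals = np.asarray(d_vals)

    if d_vals.size >= 3:
        tail = np.diff(d_vals)[-2:]
        saturated = bool(np.all(np.abs(tail) < saturation_step))
        saturation = float(np.mean(d_vals[-3:]))
    else:
        saturated = False
        saturation = float(d_vals[-1])
    return CorrelationDimensionResult(
        embedding_dims=e_range,
        d_corr=d_vals,
        saturated=saturated,
        saturation=saturation,
        curves=pd.DataFrame(rows),
    )


def _scaling_slope(radii: np.ndarray, c_of_r: np.ndarray) -> float:
    """Slope of log C vs log r over the small-r scaling region.

    Radii where C stalls (no new pairs: exactly repeated values, as in
    sample-locked periodic signals) carry no scaling information and are
    dropped before the fit.
    """
    growing = np.ones(c_of_r.size, dtype=bool)
    growing[1:] = c_of_r[1:] > c_of_r[:-1] * (1 + 1e-9)
    growing[0] = c_of_r[0] > 0
    sel = growing & (c_of_r >= 1e-3) & (c_of_r <= 1e-1)
    if sel.sum() < 5:
        sel = growing & (c_of_r > 0) & (c_of_r < 1.0)
    if sel.sum() < 2:
        raise ValueError("insufficient pairs within the radius grid")
    lr = np.log(radii[sel])
    lc = np.log(c_of_r[sel])
    return float(np.polyfit(lr, lc, 1)[0])


def permutation_entropy(y: np.ndarray, order: int = 4, delay: int = 1) -> float:
    """Normalised ordinal-pattern Shannon entropy in [0, 1].

    0 means a single ordinal pattern (e.g. a monotone ramp); 1 means all
    order! patterns equally likely (white noise in the long-series limit).
    Ties are broken by temporal order (stable sort).
    """
    y = np.asarray(y, dtype=float)
    n_windows = y.size - (order - 1) * delay
    if n_windows < 2:
        raise ValueError("trace too short for the requested pattern order")
    windows = sliding_window_view(y, (order - 1) * delay + 1)[:, ::delay]
    patterns = np.argsort(windows, axis=1, kind="stable")
    weights = (order ** np.arange(order)).astype(np.int64)
    codes = patterns @ weights
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order)))


def stationarity_test(
    y: np.ndarray, n_windows: int = 4, drift_tol: float = 1.0
) -> bool:
    """Windowed drift check: True when mean and spread are stable over time.

    The trace is cut into ``n_windows`` blocks; it is non-stationary when the
    spread of block means exceeds ``drift_tol`` overall standard deviations.
    """
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd == 0:
        return True
    blocks = np.array_split(y, n_windows)
    means = np.array([b.mean() for b in blocks])
    return bool((means.max() - means.min()) / sd <= drift_tol)


def determinism_test(
    trace,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    order: int = 4,
    delay: int = 1,
    min_points: int = 110,
    seed=None,
) -> tuple[str, str]:
    """Permutation-entropy surrogate test: "deterministic" or "stochastic".

    The trace's permutation entropy is compared with the distribution over
    randomly shuffled copies (which keep the value multiset, hence mean and
    standard deviation, but destroy temporal order). If the original entropy
    falls below the lower alpha/2 quantile of the surrogates the dynamics are
    classified deterministic; entropy within the surrogate distribution means
    the ordering carries no information beyond the value distribution, i.e.
    stochastic. Also returns a "stationary"/"non-stationary" flag from a
    windowed drift test. Traces shorter than ``min_points`` are rejected.
    """
    tr = _as_trace(trace)
    y = tr.y
    if y.size < min_points:
        raise ValueError(
            f"insufficient data: {y.size} points < required {min_points}"
        )
    if y.std() == 0:
        raise ValueError("zero-variance trace cannot be classified")
    rng = np.random.default_rng(seed)
    h0 = permutation_entropy(y, order=order, delay=delay)
    h_surr = np.array(
        [
            permutation_entropy(rng.permutation(y), order=order, delay=delay)
            for _ in range(n_surrogates)
        ]
    )
    threshold = np.quantile(h_surr, alpha / 2)
    determinism = "deterministic" if h0 < threshold else "stochastic"
    stationarity = "stationary" if stationarity_test(y) else "non-stationary"
    return determinism, stationarity


def classify_alive(growth_rate_trace, threshold: float = DEAD_GROWTH_THRESHOLD) -> bool:
    """Alive iff the mean length growth rate is not below ``threshold``."""
    tr = _as_trace(growth_rate_trace)
    return bool(np.mean(tr.y) >= threshold)


def cross_correlation(trace_a, trace_b, max_lag: int, difference: bool = True):
    """Normalised cross-correlation of two aligned traces over +/- max_lag.

    Both series are (optionally) frame-differenced and z-scored; the value at
    lag 0 is the Pearson correlation. Positive lags mean ``trace_a`` leads.
    Returns ``(lags, values)``.
    """
    a, b = _as_trace(trace_a), _as_trace(trace_b)
    if len(a) != len(b):
        raise ValueError("traces must have equal length")
    ya, yb = a.y, b.y
    if difference:
        ya, yb = np.diff(ya), np.diff(yb)
    if ya.std() == 0 or yb.std() == 0:
        raise ValueError("zero-variance signal in cross-correlation")
    ya = (ya - ya.mean()) / ya.std()
    yb = (yb - yb.mean()) / yb.std()
    n = ya.size
    max_lag = min(max_lag, n - 1)
    lags = np.arange(-max_lag, max_lag + 1)
    full = np.correlate(ya, yb, mode="full") / n
    mid = n - 1
    return lags, full[mid - max_lag : mid + max_lag + 1]


@dataclass
class ChaosReport:
    """Per-trace analysis outcome."""

    lyapunov: float | None = None
    corr_dim: CorrelationDimensionResult | None = None
    acf: np.ndarray | None = None
    acf_peak_lags: np.ndarray | None = None
    acf_period: float | None = None
    determinism_class: str | None = None
    stationarity_class: str | None = None
    alive: bool | None = None

    def to_dict(self) -> dict:
        return {
            "lyapunov": self.lyapunov,
            "corr_dim_saturation": (
                self.corr_dim.saturation if self.corr_dim else None
            ),
            "corr_dim_saturated": (
                self.corr_dim.saturated if self.corr_dim else None
            ),
            "acf_period": self.acf_period,
            "acf_peak_lags": (
                self.acf_peak_lags.tolist()
                if self.acf_peak_lags is not None
                else None
            ),
            "determinism": self.determinism_class,
            "stationarity": self.stationarity_class,
            "alive": self.alive,
        }


def analyze_trace(
    trace,
    growth_rate_trace=None,
    max_lag: int | None = None,
    difference_for_acf: bool = True,
    seed=None,
) -> ChaosReport:
    """Run the full metric battery on one trace."""
    tr = _as_trace(trace)
    report = ChaosReport()
    acf_input = difference_signal(tr) if difference_for_acf else tr
    if max_lag is None:
        max_lag = min(len(acf_input) - 2, len(acf_input) // 2)
    report.acf, report.acf_peak_lags, report.acf_period = acf_with_peaks(
        acf_input, max_lag=max_lag
    )
    report.lyapunov = lyapunov_exponent(tr)
    report.corr_dim = correlation_dimension(tr)
    report.determinism_class, report.stationarity_class = determinism_test(
        tr, seed=seed
    )
    if growth_rate_trace is not None:
        report.alive = classify_alive(growth_rate_trace)
    return report
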