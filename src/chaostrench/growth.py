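"""Adder growth with stressor-dependent elongation inhibition.

Cells elongate geometrically, ``l_{t+1} = l_t * (1 + g)``, and divide into two
equal daughters once the length added since birth exceeds the fixed increment
``L_div`` (the adder rule, which makes birth length converge to ``L_div``
regardless of initial size). The elongation rate decays sigmoidally with the
intracellular stressor concentration and halves exactly at ``c2``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model_core import CellState, ModelParameters

__all__ = ["elongation_rate", "grow_cell", "maybe_divide"]


def elongation_rate(h_cell, params: ModelParameters):
    """Elongation rate (1/min) at intracellular stressor level ``h_cell``.

    g(h) = g0 * (1 - 1 / (1 + 10^(-c1 (h - c2)))): strictly decreasing,
    g(0) just below g0, g(c2) = g0/2, and g -> 0 for h >> c2. Works on
    scalars or arrays. The same law is used for the general-model toxin.
    """
    h = np.asarray(h_cell, dtype=float)
    if np.any(h < 0):
        raise ValueError("intracellular stressor concentration must be >= 0")
    # 10^(-c1*(h - c2)) overflows for h well below c2 (c1 is huge); clip exponent.
    expo = np.clip(-params.c1 * (h - params.c2), -700.0, 700.0)
    g = params.g0 * (1.0 - 1.0 / (1.0 + np.power(10.0, expo)))
    return float(g) if np.isscalar(h_cell) else g


def grow_cell(cell: CellState, g: float, n_steps: int = 1) -> CellState:
    """Elongate a cell for ``n_steps`` outer steps at fixed rate ``g``.

    Concentrations are untouched: dilution is a -g*[X] term inside the
    response ODEs, not an explicit rescaling here.
    """
    if g < 0:
        raise ValueError("elongation rate must be >= 0")
    new = dataclasses.replace(cell)
    factor = (1.0 + g) ** n_steps
    increase = cell.length * (factor - 1.0)
    new.length = cell.length * factor
    new.added_length = cell.added_length + increase
    return new


def maybe_divide(cell: CellState, params: ModelParameters) -> list[CellState]:
    """Apply the adder division rule; returns one (no division) or two cells.

    Division is triggered by a strict inequality ``added_length > L_div``. The
    two daughters each get half the parent length, a reset adder counter, and
    identical concentrations (an equal split conserves concentration). The
    first element of the returned list is the daughter nearer the open end.
    """
    if cell.added_length > params.L_div:
        half = cell.length / 2.0
        d1 = dataclasses.replace(cell, length=half, added_length=0.0)
        d2 = dataclasses.replace(cell, length=half, added_length=0.0)
        return [d1, d2]
    return [cell]
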