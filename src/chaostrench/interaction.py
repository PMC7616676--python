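"""Steady-state reaction-diffusion attenuation of stressor along the trench.

Cells absorb the external stressor across their envelope while it diffuses
down the 1-D trench. At steady state the concentration profile along one cell
of length ``l`` obeys ``u'' = u / lambda'^2`` with a Dirichlet condition at the
source-facing pole and zero flux at the far pole, giving

    u(x) = u(0) * cosh((x - l) / lambda') / cosh(l / lambda')

The screening length ``lambda'`` accounts for rod-shaped cells (cylinders
capped with hemispheres) in a square-cross-section trench:

    lambda'^2 = (W^2 l - pi R_c^2 l + (2/3) pi R_c^3) * D / (2 pi R_c k_abs l)

Chaining the solution cell by cell from the open end yields the concentration
each cell is exposed to; absorption by cells nearer the source shields the
mother cell at the closed end.
"""

from __future__ import annotations

import math

import numpy as np

from .model_core import ModelParameters, TrenchState

__all__ = ["screening_length", "attenuate_through_cell", "trench_profile"]


def screening_length(l_t: float, params: ModelParameters) -> float:
    """Screening length lambda' (um) for a cell of length ``l_t``.

    Returns ``inf`` when k_abs = 0 (no absorption, no attenuation).
    """
    if l_t <= 0:
        raise ValueError("cell length must be > 0")
    W, Rc = params.W, params.R_c
    free_volume = (W * W - math.pi * Rc * Rc) * l_t + (2.0 / 3.0) * math.pi * Rc**3
    if free_volume <= 0:
        raise ValueError(
            "non-positive free cross-section: cell does not fit in the trench"
        )
    absorbing = 2.0 * math.pi * Rc * params.k_abs * l_t
    if absorbing == 0.0:
        return math.inf
    return math.sqrt(free_volume * params.D / absorbing)


def attenuate_through_cell(
    h_in: float, l_t: float, params: ModelParameters, n_profile: int = 0
):
    """Concentration profile along one cell and the value at its far pole.

    Local coordinate: x = 0 at the source-facing pole (concentration ``h_in``),
    x = l_t at the far pole, where the next cell starts. Returns
    ``(profile, h_out)``; ``profile`` is an array of ``n_profile`` samples over
    [0, l_t] (empty when ``n_profile`` = 0).
    """
    if h_in < 0:
        raise ValueError("external concentration must be >= 0")
    lam = screening_length(l_t, params)
    if math.isinf(lam):
        h_out = h_in
        profile = np.full(n_profile, h_in)
    else:
        ratio = l_t / lam
        h_out = h_in / math.cosh(ratio)
        if n_profile:
            x = np.linspace(0.0, l_t, n_profile)
            profile = h_in * np.cosh((x - l_t) / lam) / math.cosh(ratio)
        else:
            profile = np.empty(0)
    return profile, h_out


def trench_profile(trench: TrenchState, params: ModelParameters) -> TrenchState:
    """Assign each cell its local external concentration, open end inward.

    Cell 0 sees the boundary concentration; each following cell sees the
    previous cell's far-pole value, so the sequence is non-increasing and the
    mother receives the most attenuated concentration. Mutates and returns the
    trench.
    """
    if len(trench.cells) == 0:
        raise ValueError("trench has no cells")
    h = trench.h_boundary
    for cell in trench.cells:
        cell.h_ext_entry = h
        _, h = attenuate_through_cell(h, cell.length, params)
    return trench
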