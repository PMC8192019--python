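"""Population-vector action readout and position update with wall reflection.

The action taken each step is the rate-weighted mean of the neurons'
preferred directions, a(t) = (1/N) * sum_j rho_j * a_j.  The position is
advanced by a(t) directly; if the step would cross the circular wall, the
radial component of the step is flipped (specular reflection).  Feedforward
synapses from boundary place cells onto outward-pointing actions are masked
to zero to avoid wall-hugging artefacts.
"""

from __future__ import annotations

import numpy as np

from .arena import ArenaSpec
from .place_cells import PlaceCellArray

__all__ = ["select_action", "update_position", "boundary_mask"]


def select_action(rates: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """a(t) = (1/N) * sum_j rho_j * a_j; rates in spikes/ms, (N,2) directions."""
    return directions.T @ np.asarray(rates, float) / len(directions)


def update_position(x, a, arena: ArenaSpec) -> np.ndarray:
    """Advance the position one step, reflecting off the circular wall.

    If ``x + a`` leaves the arena the radial component of ``a`` is flipped:
    dx = a - 2*(a . x_hat)*x_hat.  Floating-point overshoot is re-projected
    onto the wall.
    """
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    nxt = x + a
    if np.linalg.norm(nxt) > arena.radius:
        r = np.linalg.norm(x)
        if r > 0:
            xh = x / r
            a = a - 2.0 * (a @ xh) * xh
        else:  # unreachable with positive radius; guard a degenerate start
            a = -a
        nxt = x + a
        n = np.linalg.norm(nxt)
        if n > arena.radius:
            nxt *= arena.radius / n
    return nxt


def boundary_mask(
    cells: PlaceCellArray, directions: np.ndarray, arena: ArenaSpec
) -> np.ndarray:
    """Boolean (n_place, N) matrix of synapses pinned to zero.

    True where the place cell lies within one lattice spacing of the wall
    (||x_i|| >= radius - sigma) and the action points outward there
    (a_j . x_i > 0, strict, so tangential actions stay unmasked).  Masked
    synapses are excluded from plasticity and from the weight bounds.
    """
    r = np.linalg.norm(cells.centers, axis=1)
    on_boundary = r >= arena.radius - cells.sigma
    outward = cells.centers @ directions.T > 0.0
    return on_boundary[:, None] & outward
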