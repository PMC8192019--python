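"""Place-cell population: Gaussian rate maps and Poisson spike generation.

121 place cells on an 11x11 lattice (spacing sigma = 0.4) tile the arena.
Cell i fires as an inhomogeneous Poisson process with rate

    lambda_i(x) = lambda_max * exp(-||x - x_i||^2 / sigma^2),

peaking at 400 Hz when the agent sits on the field centre.  Spiking is
discretised as independent per-step Bernoulli draws with p = rate * dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaSpec

__all__ = ["PlaceCellArray", "build_place_grid", "place_rates", "sample_place_spikes"]

PEAK_RATE_HZ = 400.0
SIGMA = 0.4
GRID_SIDE = 11


@dataclass(frozen=True)
class PlaceCellArray:
    centers: np.ndarray          # (n, 2) field centres, a.u.
    sigma: float = SIGMA         # field width == lattice spacing, a.u.
    peak_rate: float = PEAK_RATE_HZ

    @property
    def n(self) -> int:
        return len(self.centers)


def build_place_grid(arena: ArenaSpec | None = None) -> PlaceCellArray:
    """11x11 square lattice centred on the origin, spanning [-2, 2] per axis.

    The unique regular construction giving 121 cells at spacing 0.4; corner
    cells fall outside the circular wall but contribute negligible rate there.
    """
    half = (GRID_SIDE - 1) // 2
    axis = np.arange(-half, half + 1) * SIGMA
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return PlaceCellArray(centers=centers)


def place_rates(x, cells: PlaceCellArray) -> np.ndarray:
    """Firing rate (Hz) of every place cell at position ``x``."""
    x = np.asarray(x, float)
    d2 = np.sum((cells.centers - x) ** 2, axis=1)
    return cells.peak_rate * np.exp(-d2 / cells.sigma**2)


def sample_place_spikes(
    rates: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli spike draw for one step; ``dt`` in ms, rates in Hz.

    Requires rate*dt <= 1 for every cell (0.4 at the defaults).
    """
    p = np.asarray(rates, float) * (dt * 1e-3)
    if np.any(p > 1.0):
        raise ValueError("rate*dt exceeds 1; decrease the timestep")
    return rng.random(p.shape) < p
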