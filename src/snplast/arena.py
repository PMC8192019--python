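"""Circular open-field arena, well placement and the two-stage trial protocol.

The task emulates place learning in a circular open field: two food wells sit
in opposite inner quadrants, only one is baited, and the agent starts each
trial from the outer field, left or right of the baited quadrant.  After 8
days (10 trials/day) the bait moves to the opposite well for 12 further days
(reversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "ProtocolSpec",
    "default_arena",
    "default_protocol",
    "start_schedule",
    "classify_position",
]

#: outcome labels returned by :func:`classify_position`
NONE, REWARD, WRONG_WELL = "none", "reward", "wrong_well"


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the circular field (arbitrary units).

    The wall radius is 2.0: the task's start positions (±1.6, ±1.2) have
    norm exactly 2 and all task geometry lies inside.
    """

    radius: float = 2.0
    well_centers: tuple = ((-0.43, 0.43), (0.43, -0.43))
    well_radius: float = 0.3
    start_positions: tuple = ((-1.6, -1.2), (1.6, 1.2))

    def __post_init__(self):
        c1, c2 = (np.asarray(c, float) for c in self.well_centers)
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if not np.allclose(c1 + c2, 0.0):
            raise ValueError("well centers must be point-symmetric about the origin")
        for p in (*self.well_centers, *self.start_positions):
            if np.linalg.norm(p) > self.radius + 1e-12:
                raise ValueError(f"point {p} lies outside the arena")


@dataclass(frozen=True)
class ProtocolSpec:
    """Two-stage session protocol and simulation time constants."""

    days_initial: int = 8
    days_reversal: int = 12
    trials_per_day: int = 10
    t_max: float = 15.0          # s, trial cutoff
    consummatory: float = 300.0  # ms appended after reward detection
    dt: float = 1.0              # ms, simulation step
    #: which well index is baited in each stage
    baited_well_by_stage: dict = field(
        default_factory=lambda: {"initial": 0, "reversal": 1}
    )

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_trials(self) -> int:
        return (self.days_initial + self.days_reversal) * self.trials_per_day

    @property
    def max_steps(self) -> int:
        return int(round(self.t_max * 1000.0 / self.dt))


def default_arena() -> ArenaSpec:
    """Arena with wells at (−0.43, 0.43) and (0.43, −0.43), r = 0.3."""
    return ArenaSpec()


def default_protocol() -> ProtocolSpec:
    return ProtocolSpec()


def start_schedule(
    protocol: ProtocolSpec,
    rng: np.random.Generator,
    balanced: bool = True,
    max_run: int = 3,
) -> np.ndarray:
    """Left/right start order for one day.

    Exactly half the trials start on each side, in random order.  With
    ``balanced`` (the default, mirroring the mouse protocol) no more than
    ``max_run`` consecutive trials share a side.

    Returns an integer array of length ``trials_per_day`` (0 = left, 1 = right).
    """
    n = protocol.trials_per_day
    if n % 2:
        raise ValueError("trials_per_day must be even for a balanced schedule")
    sides = np.repeat([0, 1], n // 2)
    while True:
        order = rng.permutation(sides)
        if not balanced or _max_run_length(order) <= max_run:
            return order


def _max_run_length(seq) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def classify_position(x, arena: ArenaSpec, baited: int) -> str:
    """Classify a position as ``reward``, ``wrong_well`` or ``none``.

    Reward takes precedence if both wells somehow contained ``x``.
    """
    x = np.asarray(x, float)
    c_b = np.asarray(arena.well_centers[baited], float)
    c_o = np.asarray(arena.well_centers[1 - baited], float)
    if np.linalg.norm(x - c_b) <= arena.well_radius:
        return REWARD
    if np.linalg.norm(x - c_o) <= arena.well_radius:
        return WRONG_WELL
    return NONE
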