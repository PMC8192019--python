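"""Grid-search model fitting of (eta_ACh, eta_DA) to daily success curves.

The parameter grid crosses 11 dopamine levels (7.5e-4 to 2.75e-3 in steps of
2e-4) with 51 acetylcholine/dopamine ratios (0 to 1 in steps of 0.02),
giving 561 parameter pairs.  A *bank* holds one simulated session per grid
point per iteration; a subject is fitted by selecting, independently in each
iteration, the grid point whose daily success curve minimises the RMSE
against the subject's curve, then averaging the winners across iterations
(both the parameter pairs and their curves).

Group-level sampling draws parameter sets uniformly from polygonal regions
of the (eta_DA, ratio) plane, snapped to grid points, for power analyses of
between-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .arena import ProtocolSpec, default_protocol
from .plasticity import PlasticityParams
from .simulate import Network, run_session

__all__ = [
    "GridSpec",
    "FitResult",
    "ParameterRegion",
    "enumerate_grid",
    "rmse_daily",
    "simulate_bank",
    "fit_subject",
    "sample_group_parameters",
    "default_regions",
]


def _da_levels(start=7.5e-4, stop=2.75e-3, step=2e-4):
    n = int(round((stop - start) / step)) + 1
    return tuple(start + i * step for i in range(n))


def _ratio_levels(step=0.02):
    n = int(round(1.0 / step)) + 1
    return tuple(i * step for i in range(n))


@dataclass(frozen=True)
class GridSpec:
    eta_da_levels: tuple = field(default_factory=_da_levels)
    ratio_levels: tuple = field(default_factory=_ratio_levels)
    iterations: int = 100

    def __post_init__(self):
        for levels in (self.eta_da_levels, self.ratio_levels):
            if np.any(np.diff(levels) <= 0):
                raise ValueError("grid levels must be strictly increasing")
        if min(self.ratio_levels) < 0 or max(self.ratio_levels) > 1:
            raise ValueError("ratios must lie in [0, 1]")

    @property
    def n_points(self) -> int:
        return len(self.eta_da_levels) * len(self.ratio_levels)

    @classmethod
    def reduced(cls, da_stride: int = 2, ratio_levels=None, iterations: int = 5):
        """Desk-scale grid: every 2nd dopamine level and five interior ratios.

        The ratio axis samples the interior of [0, 1]: on the eta_ACh = 0
        line dopamine is structurally unidentifiable (reversal is uniformly
        slow without cholinergic unlearning), and that degenerate line makes
        up only 2% of the full grid, so a coarse axis through 0 would give
        it far more weight than the full design does.
        """
        full = cls()
        return cls(
            eta_da_levels=full.eta_da_levels[::da_stride],
            ratio_levels=ratio_levels or (0.1, 0.3, 0.5, 0.7, 0.9),
            iterations=iterations,
        )


def enumerate_grid(spec: GridSpec) -> np.ndarray:
    """(n_points, 2) array of (eta_ach, eta_da), eta_DA-major, ratio-minor."""
    pairs = [
        (r * da, da) for da in spec.eta_da_levels for r in spec.ratio_levels
    ]
    return np.asarray(pairs)


def rmse_daily(subject_curve, agent_curve) -> float:
    """RMSE between two daily-success curves, in percentage points."""
    a = np.asarray(subject_curve, float)
    b = np.asarray(agent_curve, float)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def simulate_bank(
    spec: GridSpec,
    seed: int,
    protocol: ProtocolSpec | None = None,
    network: Network | None = None,
    progress=None,
) -> np.ndarray:
    """Simulate the session bank: (n_points, iterations, n_days) curves.

    One session per grid point per iteration, shared by all subjects fitted
    against it.  Seeds are spawned from ``seed`` so any entry is reproducible
    in isolation.
    """
    protocol = protocol or default_protocol()
    network = network or Network.build()
    grid = enumerate_grid(spec)
    n_days = protocol.days_initial + protocol.days_reversal
    bank = np.empty((len(grid), spec.iterations, n_days))
    children = np.random.SeedSequence(seed).spawn(len(grid) * spec.iterations)
    k = 0
    for gi, (ach, da) in enumerate(grid):
        for it in range(spec.iterations):
            sess = run_session(
                PlasticityParams(eta_ach=ach, eta_da=da),
                protocol=protocol,
                seed=children[k].generate_state(1)[0] & 0x7FFFFFFF,
                network=network,
            )
            bank[gi, it] = sess.daily_success
            k += 1
            if progress is not None:
                progress(k, len(grid) * spec.iterations)
    return bank


@dataclass
class FitResult:
    subject: str
    per_iteration_best: np.ndarray  # (iterations, 3): eta_ach, eta_da, rmse
    estimate: np.ndarray            # mean (eta_ach, eta_da)
    fitted_curve: np.ndarray        # mean daily success of the winners


def fit_subject(
    subject_curve, spec: GridSpec, bank: np.ndarray, subject: str = ""
) -> FitResult:
    """Per-iteration RMSE argmin over the grid, averaged across iterations.

    Ties are broken towards the lowest eta_ACh, then the lowest eta_DA.
    """
    if bank.size == 0:
        raise ValueError("empty simulation bank")
    grid = enumerate_grid(spec)
    curve = np.asarray(subject_curve, float)
    if curve.shape[0] != bank.shape[2]:
        raise ValueError("subject curve length does not match the bank")
    best = np.empty((spec.iterations, 3))
    win_curves = np.empty((spec.iterations, bank.shape[2]))
    # tie-break order: ascending (eta_ach, eta_da)
    order = np.lexsort((grid[:, 1], grid[:, 0]))
    for it in range(spec.iterations):
        err = np.sqrt(np.mean((bank[:, it, :] - curve) ** 2, axis=1))
        gi = order[np.argmin(err[order])]
        best[it] = (grid[gi, 0], grid[gi, 1], err[gi])
        win_curves[it] = bank[gi, it]
    return FitResult(
        subject=subject,
        per_iteration_best=best,
        estimate=best[:, :2].mean(axis=0),
        fitted_curve=win_curves.mean(axis=0),
    )


@dataclass(frozen=True)
class ParameterRegion:
    """Polygon in the (eta_DA, ratio) plane from which parameters are drawn."""

    vertices: tuple  # ((eta_da, ratio), ...)

    @classmethod
    def rectangle(cls, da_lo, da_hi, ratio_lo, ratio_hi):
        return cls(
            vertices=(
                (da_lo, ratio_lo), (da_hi, ratio_lo),
                (da_hi, ratio_hi), (da_lo, ratio_hi),
            )
        )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def default_regions() -> dict:
    """Sampling regions for the group power analysis.

    Both span the full dopamine range, in the low-to-moderate acetylcholine
    regime where reversal performance improves with ACh; the light-on
    (cholinergic-silenced) region is shifted towards reduced ACh ratios.
    The numeric boundaries are a qualitative design choice (the reference
    regions are defined only graphically); see docs/methods.md.
    """
    return {
        "control": ParameterRegion.rectangle(7.5e-4, 2.75e-3, 0.10, 0.40),
        "reduced_ach": ParameterRegion.rectangle(7.5e-4, 2.75e-3, 0.00, 0.32),
    }


def sample_group_parameters(
    region: ParameterRegion,
    n: int,
    rng: np.random.Generator,
    spec: GridSpec | None = None,
) -> np.ndarray:
    """Uniform draws from the region, snapped to grid points.

    Returns an (n, 2) array of (eta_ach, eta_da) pairs.  Degenerate regions
    of zero area are allowed only if they contain at least one point
    (a single-vertex region yields identical draws).
    """
    spec = spec or GridSpec()
    da = np.asarray(spec.eta_da_levels)
    ratios = np.asarray(spec.ratio_levels)
    if len(region.vertices) == 1:
        # degenerate single-point region: snap and repeat
        pt = _snap(*region.vertices[0], da, ratios)
        return np.tile(pt, (n, 1))
    poly = region.polygon
    lo_x, lo_y, hi_x, hi_y = poly.bounds
    if poly.area == 0.0:
        raise ValueError("region must have positive area (or be a single point)")
    out = np.empty((n, 2))
    k = 0
    while k < n:
        px = rng.uniform(lo_x, hi_x)
        py = rng.uniform(lo_y, hi_y)
        if poly.covers(Point(px, py)):
            out[k] = _snap(px, py, da, ratios)
            k += 1
    return out


def _snap(da_val, ratio_val, da_levels, ratio_levels):
    d = da_levels[np.argmin(np.abs(da_levels - da_val))]
    r = ratio_levels[np.argmin(np.abs(ratio_levels - ratio_val))]
    return np.array([r * d, d])
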