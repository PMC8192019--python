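"""Trial loop and the two-stage session protocol.

A session is 8 days x 10 trials of initial place learning with the first
well baited, then 12 days x 10 trials of reversal with the opposite well
baited.  Weights persist across trials and the stage switch; all neural
activity (spike accumulators, pairing traces, eligibility) is reset between
trials.  Each trial runs at most 15 s of simulated time; finding the baited
well triggers the phasic dopamine update and a 300 ms consummatory pause
before termination, touching the empty well ends the trial immediately, and
otherwise the trial times out.

Two engines compute identical dynamics: ``engine="fast"`` (default) runs a
numba-compiled fused loop, ``engine="reference"`` steps through the
per-module NumPy operations; both consume the same random stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .action_ring import (
    ActionLayerParams,
    ActionLayerState,
    build_lateral_weights,
    estimate_rates,
    preferred_directions,
    sample_action_spikes,
    update_membrane,
)
from .arena import (
    NONE,
    REWARD,
    WRONG_WELL,
    ArenaSpec,
    ProtocolSpec,
    classify_position,
    default_arena,
    default_protocol,
    start_schedule,
)
from .navigation import boundary_mask, select_action, update_position
from .place_cells import PlaceCellArray, build_place_grid, place_rates, sample_place_spikes
from .plasticity import (
    PlasticityParams,
    PlasticityState,
    deliver_dopamine,
    init_weights,
    step_plasticity,
)

__all__ = ["Network", "TrialResult", "SessionResult", "run_trial", "run_session", "policy_map"]

_CHUNK = 2500  # steps simulated per kernel call


@dataclass(frozen=True)
class Network:
    """Static structure shared by all trials of a session."""

    arena: ArenaSpec
    cells: PlaceCellArray
    params: ActionLayerParams
    directions: np.ndarray
    lateral: np.ndarray
    mask: np.ndarray

    @classmethod
    def build(
        cls,
        arena: ArenaSpec | None = None,
        params: ActionLayerParams | None = None,
        lateral_normalised: bool = True,
    ) -> "Network":
        arena = arena or default_arena()
        params = params or ActionLayerParams()
        cells = build_place_grid(arena)
        dirs = preferred_directions(params)
        return cls(
            arena=arena,
            cells=cells,
            params=params,
            directions=dirs,
            lateral=build_lateral_weights(params, normalised=lateral_normalised),
            mask=boundary_mask(cells, dirs, arena),
        )


@dataclass
class TrialResult:
    stage: str          # "initial" | "reversal"
    day: int            # 1-based within stage
    trial: int          # 1-based within day
    start_side: str     # "left" | "right"
    outcome: str        # "reward" | "wrong_well" | "timeout"
    latency: float      # s, time to detection (excludes the consummatory pause)
    trajectory: np.ndarray | None = None


@dataclass
class SessionResult:
    eta_ach: float
    eta_da: float
    seed: int
    trials: list
    daily_success: np.ndarray   # 20 daily percentages, initial then reversal
    final_weights: np.ndarray
    day_weights: dict = field(default_factory=dict)  # (stage, day) -> weights copy


def run_trial(
    weights: np.ndarray,
    network: Network,
    protocol: ProtocolSpec,
    pparams: PlasticityParams,
    baited: int,
    start: np.ndarray,
    rng: np.random.Generator,
    engine: str = "fast",
    record_trajectory: bool = False,
) -> TrialResult:
    """Simulate one trial; ``weights`` is updated in place.

    Returns a :class:`TrialResult` with stage/day/trial fields unset (empty);
    :func:`run_session` fills them in.
    """
    if engine == "fast":
        if record_trajectory:
            raise ValueError("trajectory recording requires engine='reference'")
        outcome, latency = _run_trial_fast(
            weights, network, protocol, pparams, baited, start, rng
        )
        traj = None
    elif engine == "reference":
        outcome, latency, traj = _run_trial_reference(
            weights, network, protocol, pparams, baited, start, rng,
            record_trajectory,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return TrialResult(
        stage="", day=0, trial=0, start_side="", outcome=outcome,
        latency=latency, trajectory=traj,
    )


def _run_trial_reference(
    weights, net: Network, protocol, pparams, baited, start, rng, record
):
    dt = protocol.dt
    act = ActionLayerState(net.params)
    pst = PlasticityState(net.cells.n, net.params.n_actions)
    x = np.array(start, float)
    prev_post = np.zeros(net.params.n_actions, bool)
    traj = [x.copy()] if record else None
    for step in range(protocol.max_steps):
        rates = place_rates(x, net.cells)
        pre = sample_place_spikes(rates, dt, rng)
        u = update_membrane(act, pre, prev_post, weights, net.lateral, dt)
        post = sample_action_spikes(act, u, dt, rng)
        rho = estimate_rates(act, post, dt)
        a = select_action(rho, net.directions)
        x = update_position(x, a, net.arena)
        step_plasticity(pst, pre, post, weights, pparams, dt, net.mask)
        prev_post = post
        if record:
            traj.append(x.copy())
        hit = classify_position(x, net.arena, baited)
        if hit == REWARD:
            deliver_dopamine(pst, weights, pparams, net.mask)
            return "reward", (step + 1) * dt * 1e-3, _stack(traj)
        if hit == WRONG_WELL:
            return "wrong_well", (step + 1) * dt * 1e-3, _stack(traj)
    return "timeout", protocol.t_max, _stack(traj)


def _stack(traj):
    return None if traj is None else np.asarray(traj)


def _run_trial_fast(weights, net: Network, protocol, pparams, baited, start, rng):
    p = net.params
    n_act = p.n_actions
    n_pre = net.cells.n
    dt = protocol.dt
    x = np.array(start, float)
    ff_m = np.zeros(n_act); ff_s = np.zeros(n_act)
    lat_m = np.zeros(n_act); lat_s = np.zeros(n_act)
    rho_m = np.zeros(n_act); rho_s = np.zeros(n_act)
    last_spike = np.full(n_act, -1e30)
    pre_trace = np.zeros(n_pre); post_trace = np.zeros(n_act)
    elig = np.zeros((n_pre, n_act)); elig_g = np.ones(1)
    prev_post = np.zeros(n_act, np.uint8)
    mask = net.mask.astype(np.uint8)
    c_bait = np.asarray(net.arena.well_centers[baited], float)
    c_other = np.asarray(net.arena.well_centers[1 - baited], float)

    t0, total = 0.0, 0
    while total < protocol.max_steps:
        n = min(_CHUNK, protocol.max_steps - total)
        u01 = rng.random((n, n_pre + n_act))
        status, done = _kernel.run_chunk(
            u01, t0, x, weights, mask, net.lateral, net.directions,
            net.cells.centers, net.cells.sigma**2, net.cells.peak_rate, dt,
            ff_m, ff_s, lat_m, lat_s, rho_m, rho_s, last_spike,
            pre_trace, post_trace, elig, elig_g, prev_post,
            p.eps_scale, p.chi, p.tau_m, p.tau_s, p.tau_gamma, p.nu_gamma,
            pparams.tau_stdp, pparams.tau_e,
            p.lambda0, p.delta_u, p.theta, p.rho_scale,
            pparams.eta_ach, pparams.eta_da, pparams.w_min, pparams.w_max,
            net.arena.radius, c_bait, c_other, net.arena.well_radius,
        )
        total += done
        t0 += done * dt
        if status == _kernel.REWARD:
            return "reward", total * dt * 1e-3
        if status == _kernel.WRONG:
            return "wrong_well", total * dt * 1e-3
    return "timeout", protocol.t_max


def run_session(
    pparams: PlasticityParams,
    protocol: ProtocolSpec | None = None,
    seed: int = 0,
    network: Network | None = None,
    engine: str = "fast",
    snapshot_days: bool = False,
) -> SessionResult:
    """Run one full 80 + 120 trial session for a single simulated agent."""
    protocol = protocol or default_protocol()
    net = network or Network.build()
    n_days = protocol.days_initial + protocol.days_reversal
    n_trials = protocol.n_trials
    children = np.random.SeedSequence(seed).spawn(n_days + n_trials)
    day_rngs = [np.random.default_rng(s) for s in children[:n_days]]
    trial_rngs = [np.random.default_rng(s) for s in children[n_days:]]

    weights = init_weights(net.cells.n, net.params.n_actions, net.mask, pparams)
    trials: list[TrialResult] = []
    daily = np.zeros(n_days)
    day_weights = {}
    k = 0
    d = 0
    for stage, stage_days in (
        ("initial", protocol.days_initial),
        ("reversal", protocol.days_reversal),
    ):
        baited = protocol.baited_well_by_stage[stage]
        for day in range(1, stage_days + 1):
            sides = start_schedule(protocol, day_rngs[d])
            wins = 0
            for trial in range(1, protocol.trials_per_day + 1):
                side = sides[trial - 1]
                start = net.arena.start_positions[side]
                res = run_trial(
                    weights, net, protocol, pparams, baited, start,
                    trial_rngs[k], engine=engine,
                )
                res.stage, res.day, res.trial = stage, day, trial
                res.start_side = "left" if side == 0 else "right"
                trials.append(res)
                wins += res.outcome == "reward"
                k += 1
            daily[d] = 100.0 * wins / protocol.trials_per_day
            if snapshot_days:
                day_weights[(stage, day)] = weights.copy()
            d += 1
    return SessionResult(
        eta_ach=pparams.eta_ach,
        eta_da=pparams.eta_da,
        seed=seed,
        trials=trials,
        daily_success=daily,
        final_weights=weights,
        day_weights=day_weights,
    )


def policy_map(
    weights: np.ndarray, cells: PlaceCellArray, directions: np.ndarray
) -> np.ndarray:
    """Policy vector field: v_i = sum_j w_ij * a_j / N, one vector per cell."""
    return weights @ directions / len(directions)
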