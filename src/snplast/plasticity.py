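"""Sequentially neuromodulated STDP (sn-Plast) on the place-to-action synapses.

The coincidence of pre- and postsynaptic spikes is measured with a symmetric,
always-positive window W(dt) = exp(-|dt|/tau), tau = 10 ms; the neuromodulator
present sets the sign and rate of the weight change:

* acetylcholine (present throughout exploration): every coincidence depresses
  its synapse immediately, dw = -eta_ach * W;
* dopamine (a phasic pulse at reward): potentiates retroactively through an
  eligibility trace, a per-synapse memory of coincidences decaying with
  tau_e = 2 s, dw = +eta_da * eligibility;
* neither present: no change.

Coincidences are accumulated online with a pair of exponential traces (one
per place cell, one per action neuron), which reproduces the all-pairs
double sum over spike times exactly: each (pre, post) pair contributes
exp(-|t_post - t_pre|/tau) once, simultaneous pairs contribute 1.

Weights are clipped to [w_min, w_max] after every update; masked
(boundary) synapses are pinned at zero and never accumulate eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "stdp_window",
    "step_plasticity",
    "deliver_dopamine",
    "init_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    eta_ach: float = 0.000345  # cholinergic depression rate
    eta_da: float = 0.00115    # dopaminergic potentiation rate
    tau_stdp: float = 10.0     # ms, coincidence window
    tau_e: float = 2000.0      # ms, eligibility decay
    w_in: float = 2.0
    w_min: float = 1.0
    w_max: float = 3.0

    def __post_init__(self):
        if self.eta_ach < 0 or self.eta_da < 0:
            raise ValueError("learning rates must be nonnegative")
        if not (self.w_min <= self.w_in <= self.w_max):
            raise ValueError("w_in must lie within [w_min, w_max]")


@dataclass
class PlasticityState:
    n_pre: int
    n_post: int
    pre_trace: np.ndarray = None   # per place cell, decay tau_stdp
    post_trace: np.ndarray = None  # per action neuron, decay tau_stdp
    eligibility: np.ndarray = None  # (n_pre, n_post), decay tau_e
    da_delivered: bool = False

    def __post_init__(self):
        if self.pre_trace is None:
            self.pre_trace = np.zeros(self.n_pre)
        if self.post_trace is None:
            self.post_trace = np.zeros(self.n_post)
        if self.eligibility is None:
            self.eligibility = np.zeros((self.n_pre, self.n_post))

    def reset(self):
        """Inter-trial reset: clears activity and eligibility, not weights."""
        self.pre_trace[:] = 0.0
        self.post_trace[:] = 0.0
        self.eligibility[:] = 0.0
        self.da_delivered = False


def stdp_window(delta_t, tau: float = 10.0):
    """W(dt) = exp(-|dt|/tau): symmetric, positive, 1 at coincidence."""
    return np.exp(-np.abs(np.asarray(delta_t, float)) / tau)


def coincidence_mass(
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    tau: float,
    dt: float,
) -> np.ndarray:
    """Advance the pairing traces one step and return this step's mass.

    mass[i, j] = pre_trace_i * [post spike j] + post_trace_j * [pre spike i],
    with this step's pre spikes already in the pre trace (weight 1) so a
    simultaneous pair counts once with W(0) = 1.
    """
    d = np.exp(-dt / tau)
    state.pre_trace *= d
    state.post_trace *= d
    state.pre_trace += pre_spikes
    mass = np.outer(state.pre_trace, post_spikes) + np.outer(
        pre_spikes, state.post_trace
    )
    state.post_trace += post_spikes
    return mass


def step_plasticity(
    state: PlasticityState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    weights: np.ndarray,
    params: PlasticityParams,
    dt: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One exploration step: accumulate eligibility, apply ACh depression.

    Acetylcholine acts instantaneously and permanently at coincidence time
    (the eligibility flag is off without dopamine), so the depression is
    applied in full at this step; the same coincidence mass also enters the
    eligibility trace for a later dopamine read-out.  Returns ``weights``.
    """
    mass = coincidence_mass(
        state, pre_spikes.astype(float), post_spikes.astype(float),
        params.tau_stdp, dt,
    )
    if mask is not None:
        mass[mask] = 0.0
    state.eligibility *= np.exp(-dt / params.tau_e)
    state.eligibility += mass
    if params.eta_ach != 0.0:
        weights -= params.eta_ach * mass
        np.clip(weights, params.w_min, params.w_max, out=weights)
        if mask is not None:
            weights[mask] = 0.0
    return weights


def deliver_dopamine(
    state: PlasticityState,
    weights: np.ndarray,
    params: PlasticityParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Phasic dopamine at reward: dw = +eta_da * eligibility, then clear it.

    Each stored coincidence is read out discounted by exp(-delay/tau_e).
    Called at most once per trial.
    """
    if state.da_delivered:
        raise RuntimeError("dopamine already delivered this trial")
    weights += params.eta_da * state.eligibility
    np.clip(weights, params.w_min, params.w_max, out=weights)
    if mask is not None:
        weights[mask] = 0.0
    state.eligibility[:] = 0.0
    state.da_delivered = True
    return weights


def init_weights(
    n_pre: int, n_post: int, mask: np.ndarray | None, params: PlasticityParams
) -> np.ndarray:
    """Feedforward matrix at w_in everywhere, masked entries at zero."""
    w = np.full((n_pre, n_post), params.w_in, float)
    if mask is not None:
        w[mask] = 0.0
    return w
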