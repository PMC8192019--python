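"""Action-neuron ring: simplified Spike Response Model dynamics.

Forty neurons, each tuned to one movement direction on a ring, receive
feedforward drive from the place cells and fixed lateral connections that
excite similarly tuned and inhibit dissimilarly tuned neurons (soft
winner-take-all).  Membrane potentials are sums of EPSP kernels

    eps(t) = eps0 / (tau_m - tau_s) * (exp(-t/tau_m) - exp(-t/tau_s)),

restricted to spikes arriving after the neuron's own last spike, plus a
refractory kernel chi * exp(-(t - t_hat)/tau_m).  Spiking is a stochastic
escape process, lambda(u) = lambda0 * exp((u - theta)/du), and each neuron's
instantaneous rate estimate is its spike train filtered with a normalised
double-exponential kernel gamma.

All kernels are maintained online as pairs of exponential accumulators; a
neuron's own spike clears its input accumulators, which implements the
"only post-spike arrivals" summation bound exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActionLayerParams",
    "ActionLayerState",
    "preferred_directions",
    "build_lateral_weights",
    "epsp_kernel",
    "rate_kernel",
    "update_membrane",
    "membrane_potentials",
    "sample_action_spikes",
    "escape_rate",
    "estimate_rates",
]


@dataclass(frozen=True)
class ActionLayerParams:
    n_actions: int = 40
    a0: float = 0.08          # a.u. per step, speed scale of preferred directions
    chi: float = -5.0         # mV, refractory amplitude
    tau_m: float = 20.0       # ms, membrane time constant
    tau_s: float = 5.0        # ms, synaptic rise constant
    eps0: float = 20.0        # EPSP scale
    lambda0: float = 60.0     # Hz, firing rate at threshold
    delta_u: float = 2.0      # mV, escape-noise scale
    theta: float = 16.0       # mV, soft threshold
    w_minus: float = -300.0   # lateral inhibition total
    w_plus: float = 100.0     # lateral excitation total
    psi_lat: float = 20.0     # concentration of the lateral similarity profile
    tau_gamma: float = 50.0   # ms, rate-estimate decay constant
    nu_gamma: float = 20.0    # ms, rate-estimate rise constant

    @property
    def eps_scale(self) -> float:
        return self.eps0 / (self.tau_m - self.tau_s)

    @property
    def rho_scale(self) -> float:
        return 1.0 / (self.tau_gamma - self.nu_gamma)


@dataclass
class ActionLayerState:
    """Time-varying quantities of the ring, all per-neuron accumulators."""

    params: ActionLayerParams
    t: float = 0.0                                  # ms
    ff_m: np.ndarray = None  # feedforward arrivals filtered at tau_m
    ff_s: np.ndarray = None  # ... at tau_s
    lat_m: np.ndarray = None
    lat_s: np.ndarray = None
    rho_m: np.ndarray = None  # own spikes filtered at tau_gamma
    rho_s: np.ndarray = None  # ... at nu_gamma
    last_spike: np.ndarray = None                   # ms, -inf if never

    def __post_init__(self):
        n = self.params.n_actions
        for name in ("ff_m", "ff_s", "lat_m", "lat_s", "rho_m", "rho_s"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))
        if self.last_spike is None:
            self.last_spike = np.full(n, -np.inf)


def preferred_directions(params: ActionLayerParams) -> np.ndarray:
    """(N, 2) array of a_j = a0*(sin th_j, cos th_j), th_j = 2*pi*j/N."""
    j = np.arange(1, params.n_actions + 1)
    th = 2.0 * np.pi * j / params.n_actions
    return params.a0 * np.column_stack([np.sin(th), np.cos(th)])


def build_lateral_weights(
    params: ActionLayerParams, normalised: bool = True
) -> np.ndarray:
    """Fixed N x N lateral weights, w_jk = w_-/N + w_+ * f(j,k)/N.

    The similarity profile is von-Mises shaped, exp(psi*cos(th_j - th_k)),
    zero on the diagonal.  With ``normalised`` (default) each row of the
    off-diagonal profile is scaled to mean 1 (g = N*e^{psi cos}/sum_{k!=j}),
    which keeps the w_+/w_- budget commensurate with mV potentials
    while preserving the excite-similar / inhibit-dissimilar structure; the
    raw unnormalised profile is available with ``normalised=False``.
    """
    n = params.n_actions
    th = 2.0 * np.pi * np.arange(1, n + 1) / n
    prof = np.exp(params.psi_lat * np.cos(th[:, None] - th[None, :]))
    np.fill_diagonal(prof, 0.0)
    if normalised:
        f = n * prof / prof.sum(axis=1, keepdims=True)
    else:
        f = prof
    return params.w_minus / n + params.w_plus * f / n


def epsp_kernel(t, params: ActionLayerParams) -> np.ndarray:
    """EPSP kernel value(s) at lag ``t`` (ms); zero for t < 0."""
    t = np.asarray(t, float)
    return np.where(
        t >= 0,
        params.eps_scale * (np.exp(-t / params.tau_m) - np.exp(-t / params.tau_s)),
        0.0,
    )


def rate_kernel(t, params: ActionLayerParams) -> np.ndarray:
    """Rate-estimation kernel gamma (1/ms); integrates to 1 over t >= 0."""
    t = np.asarray(t, float)
    return np.where(
        t >= 0,
        params.rho_scale
        * (np.exp(-t / params.tau_gamma) - np.exp(-t / params.nu_gamma)),
        0.0,
    )


def update_membrane(
    state: ActionLayerState,
    place_spikes: np.ndarray,
    action_spikes: np.ndarray,
    weights: np.ndarray,
    lateral: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Advance the input accumulators one step and return the potentials.

    ``place_spikes`` (n_place,) and ``action_spikes`` (N,) are the spikes
    emitted during this step; they arrive with kernel value eps(0) = 0 and
    shape the potential from the next step on.  ``weights`` is the
    (n_place, N) feedforward matrix at arrival time.
    """
    p = state.params
    state.t += dt
    state.ff_m *= np.exp(-dt / p.tau_m)
    state.ff_s *= np.exp(-dt / p.tau_s)
    state.lat_m *= np.exp(-dt / p.tau_m)
    state.lat_s *= np.exp(-dt / p.tau_s)
    if place_spikes.any():
        drive = weights[place_spikes].sum(axis=0)
        state.ff_m += drive
        state.ff_s += drive
    if action_spikes.any():
        drive = lateral[:, action_spikes].sum(axis=1)
        # the lateral sum runs over k != j: a neuron never receives its own spike
        drive[action_spikes] -= np.diag(lateral)[action_spikes]
        state.lat_m += drive
        state.lat_s += drive
    return membrane_potentials(state)


def membrane_potentials(state: ActionLayerState) -> np.ndarray:
    p = state.params
    u = p.eps_scale * (state.ff_m - state.ff_s + state.lat_m - state.lat_s)
    refr = p.chi * np.exp(-(state.t - state.last_spike) / p.tau_m)
    return u + np.where(np.isfinite(state.last_spike), refr, 0.0)


def escape_rate(u, params: ActionLayerParams) -> np.ndarray:
    """Instantaneous firing rate (Hz) at potential ``u`` (mV)."""
    return params.lambda0 * np.exp((np.asarray(u, float) - params.theta) / params.delta_u)


def sample_action_spikes(
    state: ActionLayerState,
    potentials: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw this step's spikes and apply the own-spike reset.

    Spike probability is clipped at 1 when lambda*dt exceeds it (saturation).
    A spiking neuron records its spike time and clears all of its input
    accumulators, so earlier arrivals no longer shape its potential.
    """
    p = state.params
    prob = np.minimum(escape_rate(potentials, p) * dt * 1e-3, 1.0)
    spikes = rng.random(p.n_actions) < prob
    if spikes.any():
        state.last_spike[spikes] = state.t
        for acc in (state.ff_m, state.ff_s, state.lat_m, state.lat_s):
            acc[spikes] = 0.0
    return spikes


def estimate_rates(
    state: ActionLayerState, new_spikes: np.ndarray, dt: float
) -> np.ndarray:
    """Advance the gamma-filtered rate estimate; returns rho in spikes/ms."""
    p = state.params
    state.rho_m *= np.exp(-dt / p.tau_gamma)
    state.rho_s *= np.exp(-dt / p.nu_gamma)
    state.rho_m += new_spikes
    state.rho_s += new_spikes
    return p.rho_scale * (state.rho_m - state.rho_s)
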