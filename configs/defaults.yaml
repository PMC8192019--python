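# Task, network and plasticity constants (flat key: value).
# Values here are the package defaults, written out for reference; any
# subset may be overridden and passed to the analysis scripts via --config.

# circular open field (arbitrary units)
arena.radius: 2.0
arena.well_radius: 0.3

# two-stage session protocol
protocol.days_initial: 8
protocol.days_reversal: 12
protocol.trials_per_day: 10
protocol.t_max: 15.0        # s
protocol.consummatory: 300.0  # ms
protocol.dt: 1.0            # ms

# action ring (simplified Spike Response Model)
action.n_actions: 40
action.a0: 0.08             # a.u. per step
action.chi: -5.0            # mV
action.tau_m: 20.0          # ms
action.tau_s: 5.0           # ms
action.eps0: 20.0
action.lambda0: 60.0        # Hz
action.delta_u: 2.0         # mV
action.theta: 16.0          # mV
action.w_minus: -300.0
action.w_plus: 100.0
action.psi_lat: 20.0
action.tau_gamma: 50.0      # ms
action.nu_gamma: 20.0       # ms
lateral.normalised: true    # row-normalised similarity profile (see docs)

# sequentially neuromodulated plasticity
plasticity.eta_ach: 0.000345
plasticity.eta_da: 0.00115
plasticity.tau_stdp: 10.0   # ms
plasticity.tau_e: 2000.0    # ms
plasticity.w_in: 2.0
plasticity.w_min: 1.0
plasticity.w_max: 3.0
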