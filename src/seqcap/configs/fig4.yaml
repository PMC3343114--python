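# Bistable perceptron with correlated output, uncorrelated inputs:
# replica-theory capacity vs scaled bistable range, with simulation overlay
# (state-switching rule) and the no-state-switching control.
n_inputs: 200
trials: 10
seed: 0
max_epochs: 3000
eta: null
c_out_values: [0.0, 0.2, 0.4, 0.6]
delta_scaled_values: [0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]
delta_scaled_sim_values: [0.0, 0.5, 1.0]
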