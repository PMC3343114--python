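# Bistable perceptron with correlations in both input and output (simulation
# only; the replica theory requires uncorrelated inputs).
n_inputs: 200
trials: 10
seed: 0
max_epochs: 3000
eta: null
c_out: 0.4
c_in_values: [0.0, 0.2, 0.4, 0.6]
delta_scaled_values: [0.0, 0.5, 1.0, 1.5]
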