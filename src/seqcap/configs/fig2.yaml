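# Desk-scale sweep: capacity and weight statistics of the standard
# sign-constrained perceptron vs input/output correlation.
n_inputs: 200
trials: 10
seed: 0
max_epochs: 3000
eta: null           # default 0.01 * theta / (N f_in)
correlations: [0.0, 0.2, 0.4, 0.6, 0.8]
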