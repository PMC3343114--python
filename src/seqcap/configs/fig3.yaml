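# Desk-scale sweep: dependence on output coding level and robustness margin.
n_inputs: 200
trials: 10
seed: 0
max_epochs: 3000
eta: null
correlations: [0.0, 0.4, 0.8]
f_out_values: [0.2, 0.5]
kappa_values: [0.0, 0.5, 1.0]
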