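# Large-scale variant of fig2 (SLOW: hours on one CPU).  Use with
#   seqcap experiment fig2 --config <this file> --out-dir ...
n_inputs: 1000
trials: 10
seed: 0
max_epochs: 20000
eta: null
correlations: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
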