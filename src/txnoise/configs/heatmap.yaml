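# Overshoot heatmap (reduced desk-scale grid): fixed-parameter normalised
# covariance of the reporter pair on an 8x8 (lam, deltaP) grid per off-rate.
# Full fidelity uses 3000+ samples per pixel and takes hours per off-rate.
experiment: heatmap
pair: mature-protein
mu_values: [2, 10, 20]
lam_range: [0.5, 5]
dp_range: [0.01, 0.5]
n_lam: 8
n_dp: 8
samples: 1000
KM: 20
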