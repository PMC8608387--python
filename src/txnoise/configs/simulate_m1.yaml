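# Minimal example: constitutive maturation model with gamma transcription
# noise, dual-reporter mode on.
model: {network: M1}
params: {KN: 50, KM: 10, deltaM: 1}
noise:
  KN: {family: gamma, params: [5, 10]}
  KM: {family: gamma, params: [8, 1.25]}
cells: 500
dual_reporter: true
seed: 1
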