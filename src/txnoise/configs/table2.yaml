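# Constitutive maturation study (model M1): nascent-mature pathway reporters
# vs dual mature reporters. Maturation rate noise Gamma(8, 1.25) is built in;
# rows set the transcription-rate noise. Reduced default: 20 replicates
# (published protocol uses 100).
experiment: table2
replicates: 20
cells: 500
rows:
  - {label: "0.00", family: point, params: [50]}
  - {label: "0.10", family: scaled-beta, params: [133.33333333333334, 6, 10.5]}
  - {label: "0.20", family: gamma, params: [5, 10]}
  - {label: "0.50", family: scaled-beta, params: [300, 1.5, 7.5]}
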