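# Bursty expression study (model M4): rows are mean (lam, mu, KN, KP, deltaP);
# KM = 10 and deltaM = 1 are fixed. Scaled Beta(5,6) noise (cv2 0.1) applies
# to lam, mu, KP, deltaP and scaled Beta(3,6) (cv2 0.2) to KN.
experiment: table4
replicates: 20
cells: 500
rows:
  - [0.5, 1, 150, 2, 0.1]
  - [1, 2, 150, 2, 0.1]
  - [1, 20, 1050, 2, 0.1]
  - [2, 2, 100, 6, 0.3]
  - [2, 20, 550, 6, 0.3]
  - [10, 10, 100, 6, 0.3]
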