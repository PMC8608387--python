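# Structural-robustness check, case 1: constitutive expression with a fixed
# maturation delay; pathway (nascent-mature) vs dual mature reporters.
experiment: generality
case: 1
replicates: 5
cells: 300
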