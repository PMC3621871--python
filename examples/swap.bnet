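# two-node swap: x1 and x2 exchange values each step
targets, factors
x1, x2
x2, x1
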