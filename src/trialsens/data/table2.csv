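arm,failures,observed,randomized
c,38,89,100
t,21,91,100
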