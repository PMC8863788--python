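# Bjellqvist ionizable-group pKa set (version 1).
# Groups: protein termini and the seven ionizable side chains.
Nterm: 7.5
Cterm: 3.55
D: 4.05
E: 4.45
C: 9.0
Y: 10.0
H: 5.98
K: 10.0
R: 12.0
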