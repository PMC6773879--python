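# Water vapor CNDO molecular orbitals: label, binding energy eps_i (eV),
# atomic components as label:occupation (n from the subshell tag).
1a1	-539.7	O_1s:2.0
2a1	-32.2	O_2s:1.48;H_1s:0.52
1b2	-18.4	O_2p:1.18;H_1s:0.82
3a1	-14.7	O_2s:0.22;O_2p:1.44;H_1s:0.34
1b1	-12.6	O_2p:2.0
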