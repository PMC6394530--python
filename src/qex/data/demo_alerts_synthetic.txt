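# Synthetic demo alert set: a handful of textbook reactive/toxicophore
# functional-group SMARTS, for tests and CLI examples of the file-based
# alert-override path. Not a curated screening collection — use the default
# Brenk catalog for real work.
nitro_group        [$([NX3](=O)=O),$([NX3+](=O)[O-])]
aldehyde           [CX3H1](=O)[#6]
acyl_halide        [CX3](=O)[F,Cl,Br,I]
michael_acceptor   [CX3]=[CX3][CX3]=[OX1]
alkyl_halide       [CX4][Cl,Br,I]
isocyanate         [NX2]=[CX2]=[OX1]
epoxide            C1OC1
azo_group          [#6][NX2]=[NX2][#6]
hydrazine          [NX3][NX3]
thiol              [#6][SX2H]
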