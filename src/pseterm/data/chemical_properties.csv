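property,A,C,G,T
ring_structure,0,1,0,1
hydrogen_bond,1,0,0,1
functional_group,0,0,1,1
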