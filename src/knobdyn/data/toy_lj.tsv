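# Reduced united-atom toy table for tests: one generic type for every atom.
residue_name	atom_name	type	r_min_half_A	epsilon_kcal
*	*	CU	1.9080	0.1094
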