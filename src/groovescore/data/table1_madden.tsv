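peptide	pdb_id	dg_exp_kJ_mol
TLTSCNTSV	1HHG	-37.32
FLPSDFFPSV	1HHH	-48.45
GILGFVFTL	1HHI	-46.94
ILKEPVHGV	1HHJ	-37.60
LLFGYPVYV	1HHK	-45.48
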