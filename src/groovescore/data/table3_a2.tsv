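peptide	temperature	ic50	pdb_id
AAGIGILTV	4	0.00008	2GUO
FLWGPRALV	4	0.0000021	1QEW
ILKEPVHGV	4	0.000008	1AKJ
ILKEPVHGV	4	0.000008	1HHJ
ILKEPVHGV	4	0.000008	1P7Q
ILKEPVHGV	4	0.000008	2X4U
IMDQVPFSV	26	0.00000654	1TVH
NLVPMVATV	4	0.0000125	2X4R
NLVPMVATV	4	0.0000125	3GSN
NLVPMVATV	4	0.0000125	3GSO
SLLMWITQC	37	0.00002107	1S9W
SLLMWITQC	37	0.00002107	2BNR
SLLMWITQC	37	0.00002107	2F53
SLLMWITQC	37	0.00002107	2F54
SLLMWITQC	37	0.00002107	2P5E
SLLMWITQC	37	0.00002107	2P5W
SLLMWITQC	37	0.00002107	2PYE
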