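peptide	ic50	temperature
ADTISSYFVGKMYF	160	37
DENPVVHFFKNIVT	4.6	37
DTISSYFVGKMYFN	780	37
ENPVVHFFKNIVTA	12	37
FNLIDTKCYKLEHP	35000	37
GKMYFNLIDTKCYK	33000	37
HFFKNIVTPRTPPY	405	37
ISSYFVGKMYFNLI	1600	37
KMYFNLIDTKCYKL	68000	37
KNSADTISSYFVGK	210	37
MYFNLIDTKCYKLE	6500	37
NLIDTKCYKLEHPV	40000	37
NPVVHFFKNIVTPR	6.8	37
NSADTISSYFVGKM	330	37
SADTISSYFVGKMY	230	37
SSYFVGKMYFNLID	1600	37
SYFVGKMYFNLIDT	400	37
TISSYFVGKMYFNL	190	37
YFNLIDTKCYKLEH	15000	37
YFVGKMYFNLIDTK	33000	37
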