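# Cloverleaf templates: region lengths in nucleotides; stems are ac
# (acceptor, 7 bp), dh (DHU, 0 allowed), an (anticodon, 5 bp), tp (TPC).
# The S1 (serine-AGN) template lacks the DHU arm, as is typical for
# metazoan mitochondrial trnS1; its an5 and tp1 pair indices are fixed by
# this layout.
name	family	ac	dh	an	tp	dh_loop	an_loop	tp_loop	sp1	sp2	var	tail	anticodon_default
standard	generic	7	4	5	5	7	7	7	2	1	2	3	NNN
S1	S1	7	0	5	5	6	7	7	2	1	2	3	GCT
M	M	7	4	5	5	7	7	7	2	1	2	3	CAT
F	F	7	4	5	5	7	7	7	2	1	2	3	GAA
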