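# Pharmacophoric feature perception rules: <category>\t<SMARTS>\t<comment>
# Categories: POS_IONIZABLE, NEG_IONIZABLE, DONOR, ACCEPTOR.
# Every atom matched by a pattern receives that category as raw evidence;
# priority resolution happens later at the atom-group level.  Edit or replace
# rows to swap in an alternative perception scheme.
POS_IONIZABLE	[NX3;H2,H1,H0;+0;!$(N-[#6X3]);!$(N-a);!$(N~[!#6;!#1])]	aliphatic amine (primary/secondary/tertiary), protonatable at physiological pH
POS_IONIZABLE	[NX3][CX3]=[NX2]	amidine / guanidine nitrogen system
POS_IONIZABLE	c1c[nH]cn1	imidazole ring (protonatable)
POS_IONIZABLE	[+;!$([+]~[-])]	explicit cation not balanced by an adjacent anion
NEG_IONIZABLE	[CX3](=[OX1])[OX2H1]	carboxylic acid
NEG_IONIZABLE	[CX3](=[OX1])[OX1-]	carboxylate
NEG_IONIZABLE	[SX4](=[OX1])(=[OX1])[OX2H1]	sulfonic acid
NEG_IONIZABLE	[PX4](=[OX1])[OX2H1]	phosphonic/phosphoric acid O-H
NEG_IONIZABLE	c1nnn[nH]1	tetrazole ring (acidic N-H)
NEG_IONIZABLE	[NX3;H1;$([NX3]([CX3]=[OX1])[CX3]=[OX1])]	imide N-H (acidic)
NEG_IONIZABLE	[-;!$([-]~[+])]	explicit anion not balanced by an adjacent cation
DONOR	[#7;!H0]	any N-H (amine, amide, aniline, azole)
DONOR	[OX2H1]	hydroxyl O-H
DONOR	[SX2H1]	thiol S-H
ACCEPTOR	[OX1]	terminal oxygen (carbonyl, sulfonyl, phosphoryl, N-oxide)
ACCEPTOR	[OX2;+0]	divalent oxygen with lone pairs (hydroxyl, ether, ester)
ACCEPTOR	[nX2;H0;+0]	pyridine-type aromatic nitrogen
ACCEPTOR	[NX1]	nitrile nitrogen
ACCEPTOR	[NX2;H0;+0]	sp2 nitrogen with lone pair (imine, azo, amidine =N-)
ACCEPTOR	[NX3;H0;+0;!$(N-[#6X3]);!$(N-a)]	tertiary aliphatic amine lone pair
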