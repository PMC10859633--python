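# SNFG monosaccharide catalog: one row per residue.
# columns: name	family	shape	color_name	r	g	b	default_enantiomer
# Shapes encode the SNFG family system (circle=hexose, square=HexNAc,
# crossed_square=hexosamine, divided_diamond=hexuronate, triangle=deoxyhexose,
# divided_triangle=deoxyhexNAc, flat_rectangle=di-deoxyhexose, star=pentose,
# diamond=nonulosonate, flat_hexagon=unknown, pentagon=assigned).
Hex	hexose	circle	white	255	255	255	-
Glc	hexose	circle	blue	0	114	188	D
Man	hexose	circle	green	0	166	81	D
Gal	hexose	circle	yellow	255	212	0	D
Gul	hexose	circle	orange	244	121	32	D
Alt	hexose	circle	pink	246	158	161	L
All	hexose	circle	purple	165	67	153	D
Tal	hexose	circle	lightblue	143	204	233	D
Ido	hexose	circle	brown	161	122	77	L
HexNAc	hexnac	square	white	255	255	255	-
GlcNAc	hexnac	square	blue	0	114	188	D
ManNAc	hexnac	square	green	0	166	81	D
GalNAc	hexnac	square	yellow	255	212	0	D
GulNAc	hexnac	square	orange	244	121	32	D
AltNAc	hexnac	square	pink	246	158	161	L
AllNAc	hexnac	square	purple	165	67	153	D
TalNAc	hexnac	square	lightblue	143	204	233	D
IdoNAc	hexnac	square	brown	161	122	77	L
HexN	hexosamine	crossed_square	white	255	255	255	-
GlcN	hexosamine	crossed_square	blue	0	114	188	D
ManN	hexosamine	crossed_square	green	0	166	81	D
GalN	hexosamine	crossed_square	yellow	255	212	0	D
GulN	hexosamine	crossed_square	orange	244	121	32	D
AltN	hexosamine	crossed_square	pink	246	158	161	L
AllN	hexosamine	crossed_square	purple	165	67	153	D
TalN	hexosamine	crossed_square	lightblue	143	204	233	D
IdoN	hexosamine	crossed_square	brown	161	122	77	L
HexA	hexuronate	divided_diamond	white	255	255	255	-
GlcA	hexuronate	divided_diamond	blue	0	114	188	D
ManA	hexuronate	divided_diamond	green	0	166	81	D
GalA	hexuronate	divided_diamond	yellow	255	212	0	D
GulA	hexuronate	divided_diamond	orange	244	121	32	D
AltA	hexuronate	divided_diamond	pink	246	158	161	L
AllA	hexuronate	divided_diamond	purple	165	67	153	D
TalA	hexuronate	divided_diamond	lightblue	143	204	233	D
IdoA	hexuronate	divided_diamond	brown	161	122	77	L
dHex	deoxyhexose	triangle	white	255	255	255	-
Qui	deoxyhexose	triangle	blue	0	114	188	D
Rha	deoxyhexose	triangle	green	0	166	81	L
6dGul	deoxyhexose	triangle	orange	244	121	32	D
6dAlt	deoxyhexose	triangle	pink	246	158	161	L
6dTal	deoxyhexose	triangle	lightblue	143	204	233	D
Fuc	deoxyhexose	triangle	red	237	28	36	L
dHexNAc	deoxyhexnac	divided_triangle	white	255	255	255	-
QuiNAc	deoxyhexnac	divided_triangle	blue	0	114	188	D
RhaNAc	deoxyhexnac	divided_triangle	green	0	166	81	L
6dAltNAc	deoxyhexnac	divided_triangle	pink	246	158	161	L
6dTalNAc	deoxyhexnac	divided_triangle	lightblue	143	204	233	D
FucNAc	deoxyhexnac	divided_triangle	red	237	28	36	L
ddHex	dideoxyhexose	flat_rectangle	white	255	255	255	-
Oli	dideoxyhexose	flat_rectangle	blue	0	114	188	D
Tyv	dideoxyhexose	flat_rectangle	green	0	166	81	D
Abe	dideoxyhexose	flat_rectangle	orange	244	121	32	D
Par	dideoxyhexose	flat_rectangle	pink	246	158	161	D
Dig	dideoxyhexose	flat_rectangle	purple	165	67	153	D
Col	dideoxyhexose	flat_rectangle	lightblue	143	204	233	L
Pen	pentose	star	white	255	255	255	-
Ara	pentose	star	green	0	166	81	L
Lyx	pentose	star	yellow	255	212	0	D
Xyl	pentose	star	orange	244	121	32	D
Rib	pentose	star	pink	246	158	161	D
Sia	nonulosonate	diamond	red	237	28	36	-
Kdn	nonulosonate	diamond	green	0	166	81	D
Neu5Ac	nonulosonate	diamond	purple	165	67	153	D
Neu5Gc	nonulosonate	diamond	lightblue	143	204	233	D
Neu	nonulosonate	diamond	brown	161	122	77	D
Bac	unknown	flat_hexagon	blue	0	114	188	D
LDmanHep	unknown	flat_hexagon	green	0	166	81	-
Kdo	unknown	flat_hexagon	yellow	255	212	0	D
Dha	unknown	flat_hexagon	orange	244	121	32	D
DDmanHep	unknown	flat_hexagon	pink	246	158	161	-
MurNAc	unknown	flat_hexagon	purple	165	67	153	D
MurNGc	unknown	flat_hexagon	lightblue	143	204	233	D
Mur	unknown	flat_hexagon	brown	161	122	77	D
Api	assigned	pentagon	blue	0	114	188	D
Fru	assigned	pentagon	green	0	166	81	D
Tag	assigned	pentagon	yellow	255	212	0	D
Sor	assigned	pentagon	orange	244	121	32	L
Psi	assigned	pentagon	pink	246	158	161	D
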