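# 52 published PELDOR/CW-EPR inter-label distances for doubly spin-labeled
# T4 lysozyme (PDB 2LZM) and (H3-H4)2 histone (PDB 1TZY), with the search
# settings used per pair (thoroughness/vdw deviate from the defaults only
# where the default settings find no conformers at a site).
# epr_mean/epr_peak in angstroms; empty epr_peak = not reported.
# Histone chain letters follow the package's default mapping (H3 -> A/E,
# H4 -> B/F) and can be overridden with --chain-map.
dataset	pdb	chain_a	res_a	chain_b	res_b	epr_mean	epr_peak	thoroughness	vdw
t4l	2lzm	A	61	A	135	47.2		normal	3.4
t4l	2lzm	A	65	A	135	46.3		normal	3.4
t4l	2lzm	A	61	A	86	37.5		normal	3.4
t4l	2lzm	A	65	A	86	37.4		normal	3.4
t4l	2lzm	A	80	A	135	36.8		normal	3.4
t4l	2lzm	A	61	A	80	34		normal	3.4
t4l	2lzm	A	65	A	80	26.5		normal	3.4
t4l	2lzm	A	119	A	131	25		normal	3.4
t4l	2lzm	A	123	A	131	23		normal	3.4
t4l	2lzm	A	65	A	76	21.4		normal	3.4
t4l	2lzm	A	116	A	131	19		normal	3.4
t4l	2lzm	A	119	A	128	19		normal	3.4
t4l	2lzm	A	140	A	151	18		normal	3.4
t4l	2lzm	A	89	A	93	16		normal	3.4
t4l	2lzm	A	86	A	119	15		normal	3.4
t4l	2lzm	A	120	A	131	14		thorough	3.2
t4l	2lzm	A	127	A	151	14		normal	3.4
t4l	2lzm	A	59	A	159	41.9	42	normal	3.4
t4l	2lzm	A	60	A	90	37.8	38	normal	3.4
t4l	2lzm	A	60	A	94	25.5	26	normal	3.4
t4l	2lzm	A	60	A	109	35.2	34	normal	3.4
t4l	2lzm	A	60	A	154	34.1	34	thorough	3.4
t4l	2lzm	A	62	A	134	41.1	41	thorough	3.4
t4l	2lzm	A	64	A	122	34.1	33	normal	3.4
t4l	2lzm	A	82	A	94	30.7	32	normal	3.4
t4l	2lzm	A	82	A	132	26.3	29	normal	3.4
t4l	2lzm	A	82	A	155	35.8	38	normal	3.4
t4l	2lzm	A	83	A	123	20.5	21	normal	3.4
t4l	2lzm	A	93	A	112	26.1	26	thorough	3.2
t4l	2lzm	A	93	A	123	24.8	25	normal	3.4
t4l	2lzm	A	93	A	154	25.1	25	thorough	3.4
t4l	2lzm	A	94	A	132	31.7	32	thorough	3.4
t4l	2lzm	A	108	A	155	35.2	36	normal	3.4
t4l	2lzm	A	109	A	134	30.6	31	normal	3.4
t4l	2lzm	A	115	A	155	28.2	27	normal	3.4
t4l	2lzm	A	116	A	134	20.2	20	normal	3.4
histone	1tzy	A	46	E	46	60	60	normal	3.4
histone	1tzy	A	49	E	49	63	63	normal	3.4
histone	1tzy	A	65	E	65	70	70	normal	3.4
histone	1tzy	A	76	E	76	68	70	normal	3.4
histone	1tzy	A	90	E	90	57	59	normal	3.4
histone	1tzy	A	125	E	125	29	28	normal	3.4
histone	1tzy	B	25	F	25	73	67	normal	3.4
histone	1tzy	B	30	F	30	66	67	normal	3.4
histone	1tzy	B	45	F	45	35	33	normal	3.4
histone	1tzy	B	47	F	47	35	26	normal	3.4
histone	1tzy	B	49	F	49	45	46	normal	3.4
histone	1tzy	B	60	F	60	39	38	normal	3.4
histone	1tzy	B	63	F	63	40	46	normal	3.4
histone	1tzy	B	67	F	67	45	45	painstaking	3.4
histone	1tzy	B	71	F	71	45	43	thorough	3.0
histone	1tzy	B	82	F	82	53	51	thorough	3.0
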