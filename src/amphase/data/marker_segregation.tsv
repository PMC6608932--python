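gene	marker	expected_mother	expected_father	expected_code	observed_mother	observed_father	observed_code
VvHLH74	GAVBInd_009	147/155	155/155	lmxll	137/146	146/146	lmxll
VvBHLH74	GAVBInd_010	230/233	234/230	hkxhk	231/237	231/237	hkxhk
VvHUA2	GAVBInd_001	452/455	437/456	bbxcd	454/454	441/454	nnxnp
VvCOL10	GAVBInd_004	197/195	197/196	hkxhk	195/197	195/197	hkxhk
VvCOL10	GAVBInd_004	197/195	197/196	efxeg	194/196	195/196	efxeg
VvCOL10	GAVBInd_005	146/115	155/155	lmxll	110/142	110/110	lmxll
VvWNK6	GAVBInd_019	N/A	N/A	N/A	210/x	217/218	abxcd
VvWNK6	GAVBInd_019	N/A	N/A	N/A	210/x	x	lmxll
VvFPA	GAVBInd_007	362/353	363/365	efxeg	363/x	x	lmxll
VvGAMYBc	GAVBInd_014	401/422	435/426	abxcd	407/428	432/437	abxcd
VvGAMYBc	GAVBInd_014	401/422	435/426	abxcd	457/x	x	lmxll
VvCOL5	GAVBInd_015	196/199	199/199	lmxll	195/198	198/198	lmxll
VvTOE3	GAVBInd_016	276/275	268/275	efxeg	279/282	272/279	efxeg
VvTOE3	GAVBInd_017	139/144	144/144	lmxll	136/140	140/140	lmxll
VvPRR37b	GAVBInd_018	281/286	286/286	lmxll	281/286	286/286	lmxll
VvGAIb	GAVBInd_006	231/241	231/236	efxeg	231/245	231/237	efxeg
VvFLKa	GAVBInd_012	133/182	182/182	lmxll	128/178	178/178	lmxll
VvFLKa	GAVBInd_013	213/217	213/213	abxcd	211/215	211/215	hkxhk
VvFUL2	GAVBInd_020	N/A	N/A	N/A	443/433	414/444	abxcd
VvSVP2	GAVBInd_008	236/247	248/248	lmxll	238/244	x	lmxll
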