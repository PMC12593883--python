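subfamily	feature	name	start	end	note
D	region	hexamer	0	6	.
D	region	alu_like	6	306	.
D	region	vntr	306	861	.
D	region	sine_r	861	1351	.
D	signal	polya	1345	1351	AATAAA
E	region	hexamer	0	6	.
E	region	alu_like	6	306	.
E	region	vntr	306	861	.
E	region	sine_r	861	1351	.
E	signal	polya	1345	1351	AATAAA
F	region	hexamer	0	6	.
F	region	alu_like	6	306	.
F	region	vntr	306	861	.
F	region	sine_r	861	1351	.
F	signal	polya	1345	1351	AATAAA
F1	region	mast2	0	385	.
F1	region	alu_remnant	385	505	.
F1	region	vntr	505	1060	.
F1	region	sine_r	1060	1550	.
F1	signal	polya	1544	1550	AATAAA
F1	junction	mast2	385	385	.
F1	diagnostic	dv40	1100	1101	F=T;F1=C
F1	diagnostic	dv95	1155	1156	F=G;F1=A
F1	diagnostic	dv190	1250	1251	F=G;F1=A
F1	diagnostic	dv280	1340	1341	F=G;F1=A
F1	diagnostic	dv330	1390	1391	F=A;F1=G
F1	diagnostic	dv410	1470	1471	F=A;F1=G
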