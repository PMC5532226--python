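gene_id	group	heptapeptide	zf_type	m	n
PheWRKY1-1	group2b	WRKYGQK	C2H2	5	23
PheWRKY1-2	group2b	WRKYGQK	C2H2	5	23
PheWRKY2	group2e	WRKYGQK	C2H2	5	23
PheWRKY3-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY3-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY4	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY5-1	group2b	WRKYGQK	C2H2	5	23
PheWRKY5-2	/	WRKYGQK	/	/	/
PheWRKY7	group2c	WRKYGKK	C2H2	4	23
PheWRKY8	group2c	WRKYGQK	C2H2	4	23
PheWRKY9-1	group2b	WRKYGQK	C2H2	5	88
PheWRKY9-2	group2b	WRKYGQK	C2H2	5	23
PheWRKY10	group2c	WRKYGQK	C2H2	4	23
PheWRKY11-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY11-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY11-3	group2c	WKKYGQK	C2H2	4	24
PheWRKY12	group2e	WRKYGQK	C2H2	5	23
PheWRKY13-1	group2e	WRKYGQK	C2H2	5	23
PheWRKY13-2	group2e	WRKYGQK	C2H2	5	23
PheWRKY13-3	group2e	WRKYGQK	C2H2	5	23
PheWRKY14	group2e	WRKYGQK	C2H2	5	23
PheWRKY15-1	group3	WRKYGQK	C2HC	7	23
PheWRKY15-2	group3	WRKYGQK	C2HC	7	23
PheWRKY16	group2c	WRKYGQK	C2H2	4	23
PheWRKY17-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY17-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY17-3	/	WRKYGQK	/	/	/
PheWRKY19-1	group3	WRKYGQK	C2HC	7	23
PheWRKY19-2	group3	WRKYGQK	C2HC	7	23
PheWRKY19-3	group3	WRKYGQK	C2HC	7	23
PheWRKY21	group3	WRKYGQK	C2HC	6	23
PheWRKY22-1	group3	WRKYGQK	C2HC	7	24
PheWRKY22-2	group3	WRKYGQK	C2HC	7	24
PheWRKY24-1	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY24-2	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY25	/	/	C2H2	4	23
PheWRKY26-1	group2c	WRKYGKK	C2H2	4	23
PheWRKY26-2	group2c	WRKYGKK	C2H2	4	23
PheWRKY28	group2a	WRKYGQK	C2H2	5	23
PheWRKY29-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY29-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY29-3	group2c	WRKYGQK	C2H2	4	23
PheWRKY29-4	group2c	WRKYGQK	C2H2	4	23
PheWRKY34-1	/	WRKYGQK	/	/	/
PheWRKY34-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY35-1	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY35-2*	group1	WRKYGQK/WRKYGQK	C2H2	4	22
PheWRKY36	group2c	WRKYGQK	C2H2	4	23
PheWRKY39-1	group2e	WRKYGQK	C2H2	5	23
PheWRKY39-2	group2e	WRKYGQK	C2H2	5	23
PheWRKY39-3	group2e	WRKYGQK	C2H2	5	23
PheWRKY42	group2d	WRKYGQK	C2H2	5	23
PheWRKY43	group2b	WRKYGQK	C2H2	5	23
PheWRKY44	group3	WRKYGQK	C2HC	7	23
PheWRKY45-1	group3	WRKYGQK	C2HC	7	23
PheWRKY45-2	/	/	C2HC	7	23
PheWRKY46-1	group3	WRKYGEK	C2HC	7	23
PheWRKY46-2	group3	WRKYGEK	C2HC	7	24
PheWRKY48-1	group3	WRKYGQK	C2HC	7	23
PheWRKY48-2	group3	WRKYGQK	C2H2	5	23
PheWRKY49	group2c	WRKYGQK	C2H2	4	23
PheWRKY51-2	group2d	WRKYGQK	C2H2	5	23
PheWRKY51-1	group2d	WRKYGQK	C2H2	5	23
PheWRKY65-1	group3	WRKYGQK	C2HC	7	29
PheWRKY65-2	group3	WRKYGQK	C2HC	7	30
PheWRKY53-1	group1	WRKYGQK/WRKYGQK	C2H2	4/4	23/23
PheWRKY53-2	group1	WRKYGQK/WRKYGQK	C2H2	4/4	23/23
PheWRKY55	group3	WRKYGEK	C2HC	7	24
PheWRKY62	group2a	WRKYGQK	C2H2	5	23
PheWRKY66	group2e	WRKYGQK	C2H2	5	23
PheWRKY67-1	group2c	WRKYGKK	C2H2	4	23
PheWRKY67-2	group2c	WRKYGKK	C2H2	4	23
PheWRKY68-1	group2d	WRKYGQK	C2H2	5	23
PheWRKY68-2	/	WRKYGQK	/	/	/
PheWRKY69-1	group3	WRKYGQK	C2HC	7	23
PheWRKY69-2	group3	WRKYGQK	C2HC	7	23
PheWRKY70-1	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY70-2	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY71-1	group2a	WRKYGQK	C2H2	5	23
PheWRKY71-2	group2a	WRKYGQK	C2H2	5	23
PheWRKY72-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY72-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY72-3	group2c	WRKYGQK	C2H2	4	23
PheWRKY73-1	group2b	WRKYGQK	C2H2	5	23
PheWRKY73-2	group2b	WRKYGQK	C2H2	5	23
PheWRKY74-1	group3	WRKYGQK	C2HC	7	23
PheWRKY74-2	group3	WRKYGKK	C2H2	7	23
PheWRKY75	group3	WRKYGQK	C2HC	7	23
PheWRKY76	group2a	WRKYGQK	C2H2	5	23
PheWRKY77-1	group2c	WRKYGQK	C2H2	4	23
PheWRKY77-2	group2c	WRKYGQK	C2H2	4	23
PheWRKY78	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY79-2	/	WRKYGQK	/	/	/
PheWRKY79-1	/	WRKYGQK	/	/	/
PheWRKY80-1	group1	CRKYGQA/WRKYGQK	C2H2	4/4	23/22
PheWRKY80-2	group1	WRKYGQQ/WRKYGQK	C2H2	4/4	22/23
PheWRKY80-3	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY82	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/23
PheWRKY83-1	group2d	WRKYGQK	C2H2	5	23
PheWRKY83-2	/	WRKYGQK	/	/	/
PheWRKY83-3	group2d	WRKYGQK	C2H2	5	23
PheWRKY85-1*	group1	WRKYGQK/WRKYGQK	C2H2	4	22
PheWRKY85-2	group1	WRKYGQK/WRKYGQK	C2H2	4/4	22/22
PheWRKY88-1	group2e	WRKYGQK	C2H2	5	23
PheWRKY88-2	/	/	C2H2	5	23
PheWRKY89	group2d	WRKYGQK	C2H2	5	23
PheWRKY93	group3	WRKYGQK	C2HC	7	23
PheWRKY95	/	WRKYGQK	/	/	/
PheWRKY96-1*	group1	WRKYGQK/WRKYGQK	C2H2	4	22
PheWRKY96-2*	group1	WRKYGQK/WRKYGQK	C2H2	4	22
PheWRKY96-3*	group1	WRKYGQK/WRKYGQK	C2H2	4	22
PheWRKY97-1	group2b	WRKYGQK	C2H2	5	23
PheWRKY97-2	group2b	WRKYGQK	C2H2	5	23
PheWRKY100	group3	WRKYGQK	C2HC	7	27
PheWRK109	group2b	WRKYGQK	C2H2	4	23
PheWRKY111	group2e	WRKYGQK	C2H2	5	23
PheWRKY114-1	group3	WRKYGEK	C2HC	7	24
PheWRKY114-2	group3	WRKYGEK	C2HC	7	23
PheWRKY116	group3	WRKYGQK	C2HC	7	24
PheWRKY119	group2c	WRKYGQK	C2H2	4	23
PheWRKY125	group1	WRKYGQK/WRKFGQK	C2HC	4/4	23/23
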