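subject_id	group	QTvar	SDqt	STVqt	QTVN	QTVI	RMSSDqt
V943F-1	carrier	533.33	23.09	14.14	0.25	1.16	28.28
V943F-2	carrier	544.50	23.33	18.86	0.39	0.23	44.72
R530X-1	carrier	1200.00	34.64	24.75	0.59	-0.79	50.33
R530X-2	carrier	1166.67	34.16	21.21	0.83	-0.97	43.2
Control 1	control	100.00	10.00	7.07	0.05	-0.95	16.33
Control 2	control	100.00	10.00	3.54	0.05	-0.11	11.55
Control 3	control	266.67	16.33	7.07	0.12	1.18	16.33
Control 4	control	75.00	8.66	7.07	0.05	-0.86	16.33
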