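subject_id	group	age	sex	diagnosis	hr_bpm	qt_ms	qtc_bazett_ms	qtc_hodges_ms	rr_ms	pr_ms	qrs_ms	cardiac_axis_deg
V943F-1	carrier	51	M	LVNC	65	480	499	489	915	160	120	0
V943F-2	carrier	12	F	LVNC	90	400	489	453	700	240	100	-53
R530X-1	carrier	60	M	LVNC	95	400	503	461	665	200	100	49
R530X-2	carrier	21	M	LVNC	59	488	483	486	865	160	100	-79
Control 1	control	26	F	-	68	440	468	454	880	160	100	60
Control 2	control	29	M	-	52	440	409	426	1225	220	80	58
Control 3	control	55	M	-	44	480	411	452	1330	220	60	21
Control 4	control	29	F	-	71	400	435	419	800	200	80	59
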