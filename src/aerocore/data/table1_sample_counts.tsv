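city	year	sample_type	n_samples
Denver	2017	air	28
Denver	2018	air	3
Denver	2019	air	7
Hong Kong	2017	air	80
Hong Kong	2018	air	79
Hong Kong	2019	air	80
London	2017	air	41
London	2018	air	36
London	2019	air	40
New York	2017	air	29
New York	2018	air	48
New York	2019	air	48
Oslo	2017	air	64
Oslo	2018	air	63
Oslo	2019	air	64
Stockholm	2017	air	8
Stockholm	2018	air	32
all	2017	field_negative	4
all	2018	field_negative	3
all	2019	field_negative	3
all	2017	lab_negative	4
all	2018	lab_negative	4
all	2019	lab_negative	4
all	2017	positive	2
all	2018	positive	2
all	2019	positive	1
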