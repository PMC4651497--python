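patient	pct_overlap_sbr	pct_overlap_abr_mni	pct_overlap_abr_jhu
TBI1	0	77.4	15.0
TBI2	0	86.9	77.5
TBI3	0	36.5	50.4
TBI4	0	23.8	40.6
TBI5	0	4.9	7.4
TBI6	0	20.9	65.5
TBI7	0	40.4	84.3
TBI8	0	14.0	15.7
TBI9	0	60.7	37.2
TBI10	0	47.4	28.6
TBI11	0	45.5	48.5
TBI12	0	4.8	100.0
TBI13	0	N/A	93.1
TBI14	0	19.5	86.5
TBI15	0	5.9	16.5
TBI16	0	29.5	50.2
TBI17	0	90.9	72.8
TBI18	0	98.4	75.4
TBI19	0	37.4	43.6
TBI20	0	13.8	15.6
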