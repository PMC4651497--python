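patient	clusters_sbr	clusters_abr_mni	clusters_abr_jhu	overlap_sbr_mni	overlap_sbr_jhu	overlap_mni_jhu
TBI1	0	3	2	0	0	0
TBI2	0	4	3	0	0	0
TBI3	2	4	2	1	1	0
TBI4	1	4	7	1	1	1
TBI5	4	8	8	4	4	0
TBI6	0	6	5	0	0	0
TBI7	0	7	4	0	0	0
TBI8	2	6	4	2	2	0
TBI9	0	3	6	0	0	0
TBI10	1	10	7	0	1	0
TBI11	0	5	10	0	0	1
TBI12	0	1	2	0	0	0
TBI13	0	0	2	0	0	0
TBI14	0	2	4	0	0	0
TBI15	6	9	8	6	6	0
TBI16	1	5	5	0	1	0
TBI17	0	1	7	0	0	0
TBI18	0	1	4	0	0	0
TBI19	3	7	7	3	3	1
TBI20	4	4	4	3	3	0
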