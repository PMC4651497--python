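patient	voxels_sbr	voxels_abr_mni	voxels_abr_jhu	increase_abr_mni	increase_abr_jhu
TBI1	0	415	247	415	247
TBI2	0	472	667	472	667
TBI3	210	645	270	435	60
TBI4	193	802	1089	609	896
TBI5	3312	6190	4695	2878	1383
TBI6	0	2065	710	2065	710
TBI7	0	4270	2477	4270	2477
TBI8	778	1606	1414	828	636
TBI9	0	865	1120	865	1120
TBI10	127	1473	1711	1346	1584
TBI11	0	1339	2836	1339	2836
TBI12	0	215	328	215	328
TBI13	0	0	345	0	345
TBI14	0	400	926	400	926
TBI15	1433	2361	2015	928	582
TBI16	146	861	1114	715	968
TBI17	0	523	1943	523	1943
TBI18	0	111	1423	111	1423
TBI19	404	1297	1101	893	697
TBI20	938	928	1020	-10	82
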