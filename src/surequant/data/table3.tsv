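patient	wm_voxels_patient	misreg_voxels_abr_mni	misreg_voxels_abr_jhu	pct_misreg_abr_mni	pct_misreg_abr_jhu
TBI1	527752	75859	53688	12.5	9.5
TBI2	625444	80502	56677	13.2	10.0
TBI3	638950	79791	48797	13.1	8.6
TBI4	515464	80629	57413	13.3	10.1
TBI5	519619	83016	53590	13.7	9.4
TBI6	591886	81188	51184	13.4	9.0
TBI7	688909	82261	55971	13.5	9.9
TBI8	474424	82225	51525	13.5	9.1
TBI9	679664	79110	58091	13.0	10.2
TBI10	619657	79616	57949	13.1	10.2
TBI11	642122	72919	55168	12.0	9.7
TBI12	566821	76050	55562	12.5	9.8
TBI13	617823	75079	49328	12.4	8.7
TBI14	649398	74964	56431	12.3	9.9
TBI15	613713	89060	63087	14.7	11.1
TBI16	633477	73954	53026	12.2	9.3
TBI17	645457	93796	66432	15.4	11.7
TBI18	551298	80069	52994	13.2	9.3
TBI19	579439	94136	69478	15.5	12.2
TBI20	594236	79985	47348	13.2	8.3
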