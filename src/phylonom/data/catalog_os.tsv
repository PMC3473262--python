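id	species	length_aa	architecture	established_name	prior_names	group	group_status	proposed_name	active	activity_reason	not_family
Os01g0278600	Os	470	PD_ia-PDZ		LOC_Os01g17070;OsDegP1	Deg-like 1	like	OsDeg-like 1	no	MISSING_TRIAD_RESIDUE
Os02g0712000	Os	1092	PD-PDZ-PDZ-PD_ia-PDZ-PDZ		LOC_Os02g48180;OsDegP2	Deg7	anchored	OsDeg7	yes
Os02g0742500	Os	567	PD-PDZ-PDZ		LOC_Os02g50880;OsDegP3	Deg9	anchored	OsDeg9.1	yes
LOC_Os03g62900	Os	299	PD		OsDegP4	Deg-like 6	like	OsDeg-like 6	yes		yes
Os04g0459900	Os	445	PD-PDZ		LOC_Os04g38640;OsDegP5	Deg8	anchored	OsDeg8	yes
Os05g0147500	Os	596	PD-PDZ-PDZ		LOC_Os05g05480;OsDegP6	Deg2	anchored	OsDeg2	yes
Os05g0417100	Os	614	PD-PDZ-PDZ		LOC_Os05g34460;OsDegP7	Deg10	anchored	OsDeg10	yes
Os05g0497700	Os	722	NT-PD		LOC_Os05g41810;OsDegP8	Deg15	anchored	OsDeg15	yes
Os05g0568900	Os	437	PD-PDZ		LOC_Os05g49380;OsDegP9	Deg1	anchored	OsDeg1	yes
Os06g0234100	Os	628	PD-PDZ-PDZ		LOC_Os06g12780;OsDegP10	Deg9	anchored	OsDeg9.2	yes
Os08g0144400	Os	496	NT-PD_ia-PDZ		LOC_Os08g04920;OsDegP11	Deg-like 2	like	OsDeg-like 2	no	MISSING_TRIAD_RESIDUE
Os11g0246600	Os	472	PD-PDZ		LOC_Os11g14170;OsDegP12	Deg14	anchored	OsDeg14	yes
Os12g0141500	Os	228	PD		LOC_Os12g04740;OsDegP13	Deg-like 3	like	OsDeg-like 3	yes		yes
Os12g0141600	Os	593	PD_ia-PD_ia		LOC_Os12g04750;OsDegP14	Deg-like 4	like	OsDeg-like 4	no	MISSING_TRIAD_RESIDUE
Os12g0616600	Os	313	PD		LOC_Os12g42210;OsDegP15	Deg5	anchored	OsDeg5	yes
Os03g0608600	Os	271	PD		LOC_Os03g41170	Deg-like 5	like	OsDeg-like 5	yes		yes
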