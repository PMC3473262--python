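id	species	length_aa	architecture	established_name	prior_names	group	group_status	proposed_name	active	activity_reason	not_family
POPTR_0001s34960	Pt	429	PD-PDZ		Pt706718;PtDeg1	Deg1	anchored	PtDeg1	yes
POPTR_0014s12970	Pt	592	PD-PDZ-PDZ		Pt572750;PtDeg2.1	Deg2	anchored	PtDeg2.1	yes
POPTR_0020s00220	Pt	624	PD-PDZ-PDZ		Pt775566;PtDeg2.2	Deg2	anchored	PtDeg2.2	yes
POPTR_0011s02330	Pt	316	PD		Pt771291;PtDeg5.1	Deg5	anchored	PtDeg5	yes
POPTR_0017s03050	Pt	1128	PD-PDZ-PDZ-PD_ia-PDZ-PDZ		Pt816849;PtDeg7.1	Deg7	anchored	PtDeg7.1	yes
POPTR_0004s08740	Pt	1080	PD-PDZ-PDZ-PD_ia-PDZ-PDZ		Pt555951;PtDeg7.2	Deg7	anchored	PtDeg7.2	yes
POPTR_0004s08720	Pt	1117	PD-PDZ-PDZ-PD_ia-PDZ-PDZ		Pt714140;PtDeg7.3	Deg7	anchored	PtDeg7.3	yes
POPTR_0004s13440	Pt	465	PD-PDZ		Pt199267;PtDeg8	Deg8	anchored	PtDeg8	yes
POPTR_0015s08440	Pt	556	PD-PDZ-PDZ		Pt251989;PtDeg9.1	Deg9	anchored	PtDeg9.1	yes
POPTR_0012s07930	Pt	559	PD-PDZ-PDZ		Pt728836;Pt823359;PtDeg9.2	Deg9	anchored	PtDeg9.2	yes
POPTR_0008s07940	Pt	587	PD-PDZ-PDZ			Deg10	anchored	PtDeg10	yes
POPTR_0013s01900	Pt	422	PD-PDZ		Pt662713;Pt662714;PtDeg14.1;PtDeg14.2	Deg14	anchored	PtDeg14	yes
POPTR_0004s04650	Pt	752	NT-PD		Pt555773;PtDeg15.1	Deg15	anchored	PtDeg15.1	yes
POPTR_0011s05510	Pt	729	NT-PD		Pt266544;PtDeg15.2	Deg15	anchored	PtDeg15.2	yes
POPTR_0018s04140	Pt	356	PD_ia-PDZ		Pt787034;PtDeg17.1	Deg17	like	PtDeg17.1	no	MISSING_TRIAD_RESIDUE
POPTR_0394s00220	Pt	298	PD_ia-PDZ		Pt586371;PtDeg17.2	Deg17	like	PtDeg17.2	no	MISSING_TRIAD_RESIDUE
POPTR_0018s04150	Pt	364	PD_ia-PDZ		Pt577788;PtDeg17.3	Deg17	like	PtDeg17.3	no	MISSING_TRIAD_RESIDUE
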