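id	species	length_aa	architecture	established_name	prior_names	group	group_status	proposed_name	active	activity_reason	not_family
Cre02.g088400	Cr	530	PD-PDZ		Deg1;Deg1A	Deg1	anchored	CrDeg1.1	yes
Cre14.g630550	Cr	555	PD-PDZ		Deg13	Deg1	anchored	CrDeg1.2	yes
Cre12.g498500	Cr	462	PD-PDZ		Deg11	Deg1	anchored	CrDeg1.3	yes
Cre02.g092000	Cr	656	PD-PDZ-PDZ		Deg2	Deg2	anchored	CrDeg2	yes
Cre02.g110600	Cr	356	PD		Deg5	Deg5	anchored	CrDeg5	yes
Cre03.g180650	Cr	1108	PD-PDZ-PDZ-PD_ia-PDZ-PDZ		Deg7	Deg7	anchored	CrDeg7	yes
Cre01.g028350	Cr	436	PD-PDZ		Deg8	Deg8	anchored	CrDeg8	yes
Cre19.g752200	Cr	1353	PD-betaglycan_hydrolase			Deg9	anchored	CrDeg9.1	yes
Cre14.g617600	Cr	619	PD-PDZ-PDZ		Deg9	Deg9	anchored	CrDeg9.2	yes
Cre01.g013300	Cr	739	PD-PDZ-PDZ		Deg10	Deg10	anchored	CrDeg10	yes
Cre12.g548200	Cr	1249	NT-PD			Deg15	anchored	CrDeg15	yes
Cre07.g332050	Cr	284	PD						yes		yes
Cre13.g579900	Cr	415	PD_ia-PDZ-PDZ						no	MISSING_TRIAD_RESIDUE	
Cre03.g203730	Cr	789	PD_ia-PDZ		CrDegO				no	MISSING_TRIAD_RESIDUE	
Cre38.g785300	Cr	319	PD_ia						no	MISSING_TRIAD_RESIDUE	
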