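id	species	length_aa	architecture	established_name	prior_names	group	group_status	proposed_name	active	activity_reason	not_family
At3g27925	At	439	PD-PDZ	Deg1	DEG1	Deg1	anchored	AtDeg1	yes
At2g47940	At	607	PD-PDZ-PDZ	Deg2	DEG2	Deg2	anchored	AtDeg2	yes
At1g65630	At	559	PD-PDZ-PDZ	Deg3	DEG3	Deg3	anchored	AtDeg3	yes
At1g65640	At	518	PD-PDZ-PDZ	Deg4	DEG4	Deg4	anchored	AtDeg4	yes
At4g18370	At	323	PD	Deg5	DEG5	Deg5	anchored	AtDeg5	yes
At1g51150	At	219	PD_ia	Deg6	DEG6	Deg6	anchored	AtDeg6	no	TRUNCATED_PD
At3g03380	At	1097	PD-PDZ-PDZ-PD_ia-PDZ-PDZ	Deg7	DEG7	Deg7	anchored	AtDeg7	yes
At5g39830	At	448	PD-PDZ	Deg8	DEG8	Deg8	anchored	AtDeg8	yes
At5g40200	At	592	PD-PDZ-PDZ	Deg9	DEG9	Deg9	anchored	AtDeg9	yes
At5g36950	At	586	PD-PDZ-PDZ	Deg10	DEG10	Deg10	anchored	AtDeg10	yes
At3g16540	At	555	PD-PDZ-PDZ	Deg11	DEG11	Deg11	anchored	AtDeg11	yes
At3g16550	At	499	PD-PDZ-PDZ	Deg12	DEG12	Deg12	anchored	AtDeg12	yes
At5g40560	At	486	PD-PDZ-PDZ	Deg13	DEG13	Deg13	anchored	AtDeg13	yes
At5g27660	At	429	PD-PDZ	Deg14	DEG14	Deg14	anchored	AtDeg14	yes
At1g28320	At	709	NT-PD	Deg15	DEG15	Deg15	anchored	AtDeg15	yes
At5g54745	At	198	PD_ia	Deg16	DEG16	Deg16	anchored	AtDeg16	no	MISSING_TRIAD_RESIDUE
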