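id	species	length_aa	architecture	established_name	prior_names	group	group_status	proposed_name	active	activity_reason	not_family
Pp1s160_79V6	Pp	500	PD-PDZ			Deg1	anchored	PpDeg1.1	yes
Pp1s198_100V6	Pp	475	PD-PDZ			Deg1	anchored	PpDeg1.2	yes
Pp1s79_92V6	Pp	501	PD-PDZ			Deg1	anchored	PpDeg1.3	yes
Pp1s21_138V6	Pp	486	PD-PDZ			Deg1	anchored	PpDeg1.4	yes
Pp1s8_140V6	Pp	618	PD-PDZ-PDZ			Deg2	anchored	PpDeg2	yes
Pp1s63_95V6	Pp	362	PD			Deg5	anchored	PpDeg5	yes
Pp1s237_5V6	Pp	1076	PD-PDZ-PDZ-PD_ia-PDZ-PDZ			Deg7	anchored	PpDeg7.1	yes
Pp1s21_327V6	Pp	1072	PD-PDZ-PDZ-PD_ia-PDZ-PDZ			Deg7	anchored	PpDeg7.2	yes
Pp1s31_50V6	Pp	493	PD-PDZ			Deg8	anchored	PpDeg8	yes
Pp1s176_87V6	Pp	612	PD-PDZ-PDZ			Deg9	anchored	PpDeg9.1	yes
Pp1s1_203V6	Pp	540	PD-PDZ			Deg9	anchored	PpDeg9.2	yes
Pp1s55_7V5	Pp	651	PD-PDZ-PDZ			Deg10	anchored	PpDeg10	yes
Pp1s180_15V6	Pp	473	PD-PDZ			Deg14	anchored	PpDeg14	yes
Pp1s196_28V6	Pp	784	NT-PD			Deg15	anchored	PpDeg15	yes
Pp1s152_166V5.1	Pp	339	PD-PDZ			Deg1	group_like	PpDeg1-group-like	yes
Pp1s176_111V6	Pp	527	PD_ia-PDZ						no	MISSING_TRIAD_RESIDUE	
Pp1s67_44V6	Pp	408	PD_ia-PDZ						no	MISSING_TRIAD_RESIDUE	
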