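sequence	biopep_id	activity	ic50_um	mass_da	ranker_score
FG	7605	ACE-I inhibitor	3700.0	222.229	0.99
PF	8854	DPP-IV inhibitor		262.294	0.99
FL	8555	DPP-IV inhibitor	399.58	278.337	0.99
FY	3556	ACE-I inhibitor	25	328.347	0.98
FA	3176	DPP-IV inhibitor		236.256	0.96
FN	8778	DPP-IV inhibitor		279.281	0.95
MG	7609	ACE-I inhibitor	4800	206.25	0.94
PG	7625	ACE-I inhibitor	17000	172.169	0.88
PG	8855	DPP-IV inhibitor		172.169	0.88
PG	3285	other		172.169	0.88
MR	8836	DPP-IV inhibitor		305.386	0.85
PL	7513	ACE-I inhibitor	337.32	228.277	0.81
PL	8638	DPP-IV inhibitor		228.277	0.81
PLG	7510	ACE-I inhibitor	4.74	285.329	0.8
PR	3537	ACE-I inhibitor	4.10	271.305	0.79
RG	8882	DPP-IV inhibitor		231.24	0.74
LG	7619	ACE-I inhibitor	8800	188.212	0.72
MA	3173	DPP-IV inhibitor		220.277	0.69
RL	8886	DPP-IV inhibitor		287.348	0.63
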