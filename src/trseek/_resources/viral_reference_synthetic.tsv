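cdr3	v.segm	antigen.species
CASSLKHKVRF	TRBV22	InfluenzaA
CASSHYYERMHVF	TRBV27	CMV
CASSWLCCNGVAGACF	TRBV15	EBV
CASSDKQHDQDEF	TRBV6	SARS-CoV-2
CASSHRTPAKEF	TRBV6	InfluenzaA
CASSGCYTADNWDSF	TRBV12	CMV
CASSCWKCPEYTQMF	TRBV18	EBV
CASSAYQMWTCF	TRBV18	SARS-CoV-2
CASSISRCWPF	TRBV6	InfluenzaA
CASSSVGKPGGDSF	TRBV28	CMV
CASSAERGRRWF	TRBV28	EBV
CASSIWTQYEYRF	TRBV2	SARS-CoV-2
CASSMCPYMNSF	TRBV11	InfluenzaA
CASSCWCRSNF	TRBV19	CMV
CASSRKWKLMKKF	TRBV20	EBV
CASSYEHRKVVF	TRBV6	SARS-CoV-2
CASSKDSIKAENSKLF	TRBV7	InfluenzaA
CASSLIMMGFNAIFF	TRBV6	CMV
CASSRYALYVNETAF	TRBV22	EBV
CASSTKMGDPAACWF	TRBV9	SARS-CoV-2
CASSTQPTMCMVNGWF	TRBV20	InfluenzaA
CASSFKYDPPF	TRBV27	CMV
CASSLVPQDKFKKF	TRBV10	EBV
CASSVCSNILHLVF	TRBV14	SARS-CoV-2
CASSTWPMNVHVHF	TRBV4	InfluenzaA
CASSMRSHVFMWVF	TRBV20	CMV
CASSPLMRADQQRSF	TRBV30	EBV
CASSGPSQQQNF	TRBV26	SARS-CoV-2
CASSVPKETYEGRQF	TRBV22	InfluenzaA
CASSWWVWSRNF	TRBV30	CMV
CASSKKLNYCTIF	TRBV13	EBV
CASSYRHHDTF	TRBV18	SARS-CoV-2
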