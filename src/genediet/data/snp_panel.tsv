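snp_id	risk_allele	trait	risk_allele_freq
rs9939609	A	BMI	0.41
rs2568958	A	BMI	0.62
rs7138803	A	BMI	0.38
rs7647305	C	BMI	0.79
rs6602024	A	BMI	0.21
rs7700000	A	BMI	0.71
rs7700001	C	BMI	0.48
rs7700002	G	BMI	0.11
rs7700003	T	BMI	0.41
rs7700004	A	BMI	0.11
rs7700005	C	BMI	0.71
rs7700006	G	BMI	0.31
rs7700007	T	BMI	0.36
rs7700008	A	BMI	0.56
rs7700009	C	BMI	0.24
rs7700010	G	BMI	0.28
rs7700011	T	BMI	0.1
rs7700012	A	BMI	0.16
rs7700013	C	BMI	0.69
rs7700014	G	BMI	0.57
rs7700015	T	BMI	0.34
rs7700016	A	BMI	0.12
rs7700017	C	BMI	0.62
rs7700018	G	BMI	0.5
rs7700019	T	BMI	0.62
rs7700020	A	BMI	0.3
rs7700021	C	BMI	0.19
rs7700022	G	BMI	0.28
rs7700023	T	BMI	0.7
rs7700024	A	BMI	0.71
rs7700025	C	WC	0.5
rs7700026	G	WC	0.44
rs7700027	T	WC	0.73
rs7700028	A	WC	0.38
rs7700029	C	WC	0.32
rs7700030	G	WC	0.38
rs7700031	T	WHR_BMI	0.51
rs7700032	A	WHR_BMI	0.55
rs7700033	C	WHR_BMI	0.63
rs7700034	G	WHR_BMI	0.28
rs7700035	T	WHR_BMI	0.5
rs7700036	A	WHR_BMI	0.71
rs7700037	C	WHR_BMI	0.48
rs7700038	G	WHR_BMI	0.2
rs7700039	T	WHR_BMI	0.49
rs7700040	A	WHR_BMI	0.46
rs7700041	C	WHR_BMI	0.73
rs7700042	G	BMI,WHR_BMI	0.48
rs7700043	T	BMI,WHR_BMI	0.44
rs7700044	A	BMI,WHR_BMI	0.18
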