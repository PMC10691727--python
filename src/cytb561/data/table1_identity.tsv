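accession	species	group	Dcytb	Lcytb	CGcytb	TScytb	CYB561D1	SDR2
NP_728727.1	Dm	CG1275	45.7	40.6	39.3	21.7	20.3	16.7
XP_315519.4	Ag	CG1275	43.2	43.2	43.4	23.2	20.4	18.6
NP_001155374.1	Ap	CG1275	32.6	34.1	40.7	17.9	23.6	15.3
NP_001280323.1	Ap	CG1275	31.7	29.6	32.4	15.2	18.6	15.5
XP_001950854.1	Ap	CG1275	37	37	41.5	22	25.5	18.1
XP_003246890.1	Ap	CG1275	30.4	31.2	33.3	17.7	20.6	11.7
XP_006572086.1	Am	CG1275	49.3	44.9	43	22	20.6	20.1
XP_026462102.1	Cf	CG1275	39.9	38.5	42.1	21.2	21.2	18.9
XP_002426701.1	Ph	CG1275	46.8	43.9	44.1	22.5	21.1	20.4
XP_008194670.1	Tc	CG1275	44.9	42.8	45.9	24.5	20.3	16.1
XP_021935166.1	Zn	CG1275	42	41.3	44.4	21.3	20.6	20.8
NP_725208.1	Dm	Nemy	35	35.7	32.1	19.7	21.8	16.4
XP_314126.2	Ag	Nemy	38.6	39.3	35.8	19	23.2	19.2
XP_001949276.1	Ap	Nemy	33.6	32.9	36.6	23.1	27.3	17
XP_026473332.1	Cf	Nemy	37.3	39.4	39.6	21.5	29.9	16.9
NP_001298968.1	Px	Nemy	37.1	37.9	38.7	23.2	19	16.4
XP_002430226.1	Ph	Nemy	35.2	36.6	35.3	20.8	26.4	15.5
XP_008198104.1	Tc	Nemy	36.6	39.4	36.7	22.9	29.2	14.9
XP_021939496.1	Zn	Nemy	39.2	38.5	38.6	22.8	28.3	14.6
NP_611079.2	Dm	CG8399	18.4	17	17.1	13.9	13.9	37
XP_314065.2	Ag	CG8399	18.3	20.4	19.9	16.1	15.4	36.8
XP_314066.4	Ag	CG8399	18.3	19	19.1	11	15.2	41.2
XP_001950579.2	Ap	CG8399	20	16.6	18.1	10.1	14.2	36.5
XP_396579.3	Am	CG8399	15.6	21.3	15.7	9.7	11.1	41.2
XP_026481553.1	Cf	CG8399	19	17.6	17	11.7	16.6	43.4
XP_013164083.1	Px	CG8399	15.6	19.1	18.6	16	17.4	39.4
XP_002423127.1	Ph	CG8399	16.4	19.9	17.2	9.4	14.1	40.1
XP_015836986.1	Tc	CG8399	17.6	17.6	15.6	11.7	15.2	38.2
XP_021919699.1	Zn	CG8399	15.5	18.3	17	12.4	15.2	41.9
NP_609982.1	Dm	Group 4B	17.1	17.1	18.7	24.8	22	10.6
NP_609990.1	Dm	Group 4B	14.3	16.4	15.8	22.7	20.6	14.2
NP_609989.1	Dm	Group 4B	18.4	14.2	16.4	19.7	16.9	14.2
NP_609986.1	Dm	Group 4B	17.3	20.9	23.2	21.1	18.3	11.2
NP_570039.1	Dm	Group 4B	18.8	22.2	19.6	24.5	21.8	11.4
XP_320673.4	Ag	Group 4A	21.5	20.1	23.1	33.1	31.7	19.4
XP_001238089.2	Ag	Group 4B	16.4	14.3	12.9	25	25.7	12.6
XP_552919.3	Ag	Group 4B	18.6	19.3	18	27.3	21.6	16.1
XP_001122176.1	Am	Group 4A	18.6	17.9	13.7	27.9	19.3	17.5
XP_003249671.1	Am	Group 4B	20.4	21.1	19.1	25.2	20.9	16.2
XP_026469480.1	Cf	Group 4A	22.3	20.1	19.6	31.7	27.3	15.5
XP_026469242.1	Cf	Group 4A	22.3	18.7	15.2	28.8	26.6	18.2
XP_013174961.1	Px	Group 4A	20	16.4	23	33.1	26.6	14.7
XP_013172799.1	Px	Group 4B	15.8	12.9	16.7	26.2	20.6	10
XP_013172813.1	Px	Group 4B	17.3	15.1	16.8	25.5	22	12.9
XP_013162691.1	Px	Group 4B	17.1	19.3	17.3	22	20.6	13.4
XP_013162686.1	Px	Group 4B	14.3	13.6	12.2	19.9	16.3	12.8
XP_013172802.1	Px	Group 4B	17.4	15.2	15.3	18.8	18.1	12
XP_013172804.1	Px	Group 4B	20.7	22.1	18	19.9	21.3	14.9
XP_008201603.1	Tc	Group 4A	23	20.1	19.6	33.1	23.7	18.3
XP_008195477.1	Tc	Group 4B	16.3	19.1	16.4	26.2	22.7	16
XP_015837014.1	Tc	Group 4B	20.7	20	18	26.8	21.8	11.2
XP_974632.1	Tc	Group 4B	17.9	18.6	16.5	21.3	22	14.8
XP_974652.1	Tc	Group 4B	20.9	18.7	15.2	26.6	24.5	14.2
XP_021927739.1	Zn	Group 4A	20.9	18	18.8	32.4	30.9	14.8
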