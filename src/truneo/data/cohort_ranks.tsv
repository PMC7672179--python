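patient_id	method	rank	candidate_id	immunogenic
P01	TruNeo	1	E01	1
P01	TruNeo	2	E02	1
P02	TruNeo	1	E03	1
P02	TruNeo	3	E04	1
P03	TruNeo	2	E05	1
P03	TruNeo	4	E06	1
P04	TruNeo	6	E07	1
P04	TruNeo	7	E08	1
P05	TruNeo	8	E09	1
P05	TruNeo	9	E10	1
P06	TruNeo	12	E11	1
P06	TruNeo	15	E12	1
P07	TruNeo	18	E13	1
P08	TruNeo	25	E14	1
P09	TruNeo	30	E15	1
P10	TruNeo	40	E16	1
P11	TruNeo	50	E17	1
P12	TruNeo	60	E18	1
P13	TruNeo	80	E19	1
P01	TruNeo	3	D001	0
P02	TruNeo	2	D002	0
P03	TruNeo	1	D003	0
P01	MHCflurry	2	E01	1
P01	MHCflurry	11	E02	1
P02	MHCflurry	3	E03	1
P02	MHCflurry	13	E04	1
P03	MHCflurry	4	E05	1
P03	MHCflurry	21	E06	1
P04	MHCflurry	5	E07	1
P04	MHCflurry	16	E08	1
P05	MHCflurry	22	E09	1
P05	MHCflurry	23	E10	1
P06	MHCflurry	19	E11	1
P06	MHCflurry	24	E12	1
P07	MHCflurry	25	E13	1
P08	MHCflurry	26	E14	1
P09	MHCflurry	27	E15	1
P10	MHCflurry	28	E16	1
P11	MHCflurry	29	E17	1
P12	MHCflurry	30	E18	1
P13	MHCflurry	31	E19	1
P01	NetMHCpan4	1	E01	1
P01	NetMHCpan4	3	E02	1
P02	NetMHCpan4	7	E03	1
P02	NetMHCpan4	2	E04	1
P03	NetMHCpan4	12	E05	1
P03	NetMHCpan4	5	E06	1
P04	NetMHCpan4	14	E07	1
P04	NetMHCpan4	21	E08	1
P05	NetMHCpan4	11	E09	1
P05	NetMHCpan4	22	E10	1
P06	NetMHCpan4	15	E11	1
P06	NetMHCpan4	23	E12	1
P07	NetMHCpan4	17	E13	1
P08	NetMHCpan4	25	E14	1
P09	NetMHCpan4	26	E15	1
P10	NetMHCpan4	27	E16	1
P11	NetMHCpan4	28	E17	1
P12	NetMHCpan4	29	E18	1
P13	NetMHCpan4	30	E19	1
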