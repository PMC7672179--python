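method	rank	peptide	elispot
TruNeo	1	SEIISFKSL	1
TruNeo	2	AEVPENVFL	0
TruNeo	3	SEHGFGPSL	1
TruNeo	4	VEWLGRCIL	1
TruNeo	5	QQMGLLTRV	0
TruNeo	6	REEKIHDLAL	1
TruNeo	7	LLCKMINLSK	0
TruNeo	8	SSEIISFKSL	1
TruNeo	9	STVPLDTLK	0
TruNeo	10	LEEEINRKM	0
MHCflurry	1	SLFWQTAMV	0
MHCflurry	2	LQFEYTFEI	0
MHCflurry	3	LLLCGVQAV	0
MHCflurry	4	ITAEIFMEK	0
MHCflurry	5	ATSPASASK	1
MHCflurry	6	MLICCCCTL	1
MHCflurry	7	ATHPIICFR	0
MHCflurry	8	STVPLDTLK	0
MHCflurry	9	LTVETLTKV	0
MHCflurry	10	HLEDFLLHI	0
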