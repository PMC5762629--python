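	Eilot	Elifaz Samar	Yotvata Grofit	Faran	Idan	Tlalim	Gilat	Avigdor	Maale Hahamisha Ramat Rachel	Hulda	Gaash	Beit Alfa	Ein Hamifratz	Dafna Amir
Eilot	0.0	0.0115	-0.0005	0.0007	-0.0029	0.0066	0.0188	0.0103	0.0151	0.0117	0.0269	0.0283	0.0248	0.0245
Elifaz Samar	0.0115	0.0	0.0015	0.0032	0.0065	-0.0046	0.0019	0.0097	0.015	0.0022	0.0026	0.0071	-0.0043	0.0069
Yotvata Grofit	-0.0005	0.0015	0.0	0.0052	-0.0028	0.0008	0.0054	0.0055	0.0207	0.0049	0.0124	0.0164	0.0124	0.0121
Faran	0.0007	0.0032	0.0052	0.0	0.0075	0.0104	0.0069	0.0034	0.0023	0.0083	0.0154	0.0041	0.0094	0.0066
Idan	-0.0029	0.0065	-0.0028	0.0075	0.0	0.0099	0.0092	0.0038	0.0061	0.0039	0.0068	0.015	0.0099	0.0128
Tlalim	0.0066	-0.0046	0.0008	0.0104	0.0099	0.0	0.0042	0.0045	0.0272	0.0001	0.0118	0.0212	0.0122	0.0066
Gilat	0.0188	0.0019	0.0054	0.0069	0.0092	0.0042	0.0	-0.0021	0.0169	-0.0001	-0.0027	0.0015	-0.0008	-0.0056
Avigdor	0.0103	0.0097	0.0055	0.0034	0.0038	0.0045	-0.0021	0.0	0.0044	0.0014	0.0069	0.0041	0.0093	0.0031
Maale Hahamisha Ramat Rachel	0.0151	0.015	0.0207	0.0023	0.0061	0.0272	0.0169	0.0044	0.0	0.0044	0.0238	0.0199	0.0159	0.0292
Hulda	0.0117	0.0022	0.0049	0.0083	0.0039	0.0001	-0.0001	0.0014	0.0044	0.0	0.0064	0.0106	0.0102	0.0069
Gaash	0.0269	0.0026	0.0124	0.0154	0.0068	0.0118	-0.0027	0.0069	0.0238	0.0064	0.0	0.0069	0.0026	0.0034
Beit Alfa	0.0283	0.0071	0.0164	0.0041	0.015	0.0212	0.0015	0.0041	0.0199	0.0106	0.0069	0.0	-0.0008	-0.0002
Ein Hamifratz	0.0248	-0.0043	0.0124	0.0094	0.0099	0.0122	-0.0008	0.0093	0.0159	0.0102	0.0026	-0.0008	0.0	-0.0004
Dafna Amir	0.0245	0.0069	0.0121	0.0066	0.0128	0.0066	-0.0056	0.0031	0.0292	0.0069	0.0034	-0.0002	-0.0004	0.0
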