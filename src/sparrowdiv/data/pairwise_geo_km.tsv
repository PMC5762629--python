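	Eilot	Elifaz Samar	Yotvata Grofit	Faran	Idan	Tlalim	Gilat	Avigdor	Maale Hahamisha Ramat Rachel	Hulda	Gaash	Beit Alfa	Ein Hamifratz	Dafna Amir
Eilot	0.0	23.7	36.3	89.9	139.8	157.3	195.1	236.6	248.3	249.1	294.0	328.3	368.4	409.5
Elifaz Samar	23.7	0.0	12.7	66.2	116.1	135.0	173.1	214.0	224.9	226.1	271.1	304.7	345.1	385.8
Yotvata Grofit	36.3	12.7	0.0	53.7	103.5	124.3	162.6	202.9	212.9	214.6	259.6	292.4	333.2	373.4
Faran	89.9	66.2	53.7	0.0	49.9	77.2	115.2	152.7	159.9	163.0	208.0	238.7	280.2	319.7
Idan	139.8	116.1	103.5	49.9	0.0	52.1	82.2	111.5	112.6	118.7	163.0	189.4	232.4	270.1
Tlalim	157.3	135.0	124.3	77.2	52.1	0.0	38.4	79.5	97.2	93.3	137.5	180.1	214.1	261.3
Gilat	195.1	173.1	162.6	115.2	82.2	38.4	0.0	43.8	70.4	60.3	102.2	151.7	180.4	231.2
Avigdor	236.6	214.0	202.9	152.7	111.5	79.5	43.8	0.0	36.9	18.6	58.5	110.6	136.6	188.6
Maale Hahamisha Ramat Rachel	248.3	224.9	212.9	159.9	112.6	97.2	70.4	36.9	0.0	21.8	53.2	83.0	120.3	164.1
Hulda	249.1	226.1	214.6	163.0	118.7	93.3	60.3	18.6	21.8	0.0	45.0	92.2	120.9	171.0
Gaash	294.0	271.1	259.6	208.0	163.0	137.5	102.2	58.5	53.2	45.0	0.0	65.2	78.8	134.5
Beit Alfa	328.3	304.7	292.4	238.7	189.4	180.1	151.7	110.6	83.0	92.2	65.2	0.0	53.1	81.5
Ein Hamifratz	368.4	345.1	333.2	280.2	232.4	214.1	180.4	136.6	120.3	120.9	78.8	53.1	0.0	62.4
Dafna Amir	409.5	385.8	373.4	319.7	270.1	261.3	231.2	188.6	164.1	171.0	134.5	81.5	62.4	0.0
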