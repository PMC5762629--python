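name,region,type,date,latitude,longitude,altitude
Eilot,Eilat,Petting zoo,2015-03-03,29.5835,34.9604,89
Elifaz,Eilat,Dairy farm,2013-04-17,29.7928,35.0106,121
Samar,Eilat,Dairy farm,2013-04-16,29.8294,35.0238,92
Yotvata,Eilat,Dairy farm,2015-03-02,29.8995,35.0596,86
Grofit,Eilat,Dairy farm,2013-04-15,29.9393,35.0635,141
Faran,Negev,Dairy farm,2015-03-04,30.3776,35.1503,94
Idan,Negev,Dairy farm,2015-02-22,30.814,35.2768,-174
Tlalim,Negev,Dairy farm,2015-02-23,30.9929,34.7735,364
Gilat,Negev,Dairy farm,2015-06-15,31.3225,34.6507,138
Avigdor,Center,Dairy farm,2014-11-09,31.7094,34.7439,65
Ramat Rachel,Center,Petting zoo,2015-03-26,31.741,35.2165,809
Maale Hahamisha,Center,Dairy farm,2014-12-28,31.8197,35.1115,805
Hulda,Center,Horse stable,2015-01-28,31.8293,34.8818,121
Gaash,Center,Petting zoo,2015-01-02,32.2323,34.8252,23
Beit Alfa,North,Dairy farm,2015-04-05,32.5171,35.4315,-85
Ein Hamifratz,North,Dairy farm,2015-01-11,32.904,35.0972,6
Amir,North,Dairy farm,2015-04-06,33.177,35.6236,76
Dafna,North,Dairy farm,2015-04-06,33.2299,35.6421,141
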