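population,locality
Eilot,Eilot
Elifaz Samar,Elifaz
Yotvata Grofit,Yotvata
Faran,Faran
Idan,Idan
Tlalim,Tlalim
Gilat,Gilat
Avigdor,Avigdor
Maale Hahamisha Ramat Rachel,Maale Hahamisha
Hulda,Hulda
Gaash,Gaash
Beit Alfa,Beit Alfa
Ein Hamifratz,Ein Hamifratz
Dafna Amir,Dafna
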