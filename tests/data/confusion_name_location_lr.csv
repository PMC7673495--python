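,Ab,Ch,En,Fr,Ir,It,Jp,Others,Ru,Sc
Ab,14575,6,970,994,419,8,9,220,14,553
Ch,16,2596,112,23,20,0,7,22,0,21
En,539,34,176509,5697,26957,38,5,8002,45,15961
Fr,821,3,6114,280663,3362,59,2,1877,13,1554
Ir,315,20,43806,4455,110699,35,3,3693,19,18132
It,17,1,193,401,80,1057,2,85,1,35
Jp,8,18,34,5,6,4,678,25,2,10
Others,313,31,20945,4188,5413,55,11,49759,145,3207
Ru,15,1,147,47,53,2,2,443,2592,35
Sc,352,10,28155,2405,18917,17,3,2721,5,89924
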