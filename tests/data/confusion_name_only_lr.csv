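,Ab,Ch,En,Fr,Ir,It,Jp,Others,Ru,Sc
Ab,6686,47,3975,2875,1448,13,37,942,18,1727
Ch,64,2515,99,56,33,0,5,25,0,20
En,516,27,172172,7881,27580,38,7,8729,34,16803
Fr,468,10,9116,276346,3965,82,9,2489,22,1961
Ir,333,14,52884,5263,98675,27,7,3654,15,20305
It,20,1,186,524,82,922,4,87,1,45
Jp,64,12,30,50,17,4,565,34,2,12
Others,339,32,23599,6106,5171,48,11,45207,196,3358
Ru,16,0,203,126,65,3,1,650,2234,39
Sc,260,10,31015,2986,19495,12,3,2709,14,86005
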