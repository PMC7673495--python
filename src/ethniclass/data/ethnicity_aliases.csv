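raw,primary,subgroup
aboriginal,Ab,
indian,Ab,Ab-Fn
first nations,Ab,Ab-Fn
first nation,Ab,Ab-Fn
cree,Ab,Ab-Fn
ojibwa,Ab,Ab-Fn
ojibway,Ab,Ab-Fn
ojibwe,Ab,Ab-Fn
mohawk,Ab,Ab-Fn
micmac,Ab,Ab-Fn
mi'kmaq,Ab,Ab-Fn
blackfoot,Ab,Ab-Fn
iroquois,Ab,Ab-Fn
salish,Ab,Ab-Fn
haida,Ab,Ab-Fn
dene,Ab,Ab-Fn
metis,Ab,Ab-Mé
métis,Ab,Ab-Mé
half breed,Ab,Ab-Mé
halfbreed,Ab,Ab-Mé
inuit,Ab,Ab-In
eskimo,Ab,Ab-In
esquimaux,Ab,Ab-In
native,Ab,Ab-other
chinese,Ch,
china,Ch,
chineese,Ch,
english,En,
england,En,
anglais,En,
french,Fr,
france,Fr,
french canadian,Fr,
francais,Fr,
français,Fr,
canadien,Fr,
acadian,Fr,
irish,Ir,
ireland,Ir,
irlandais,Ir,
italian,It,
italy,It,
italien,It,
japanese,Jp,
japan,Jp,
japaneese,Jp,
russian,Ru,
russia,Ru,
russe,Ru,
scottish,Sc,
scotch,Sc,
scotish,Sc,
scotland,Sc,
ecossais,Sc,
german,Others,
dutch,Others,
swedish,Others,
norwegian,Others,
polish,Others,
ukrainian,Others,
welsh,Others,
american,Others,
jewish,Others,
other,Others,
others,Others,
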