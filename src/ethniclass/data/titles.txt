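# Personal titles stripped from names during cleaning (one per line, lowercase,
# punctuation-free). Editable: the historical census transcription conventions
# are not fully enumerable, so extend as needed.
mr
mrs
miss
ms
master
dr
doctor
rev
reverend
fr
father
sr
sister
sir
lady
lord
capt
captain
col
colonel
maj
major
lt
lieut
lieutenant
sgt
sergeant
gen
general
hon
honourable
prof
professor
jr
junior
esq
esquire
widow
wid
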