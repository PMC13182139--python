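#outgroup=O
# Palaeognath clade assignment: 14 ingroup species in 5 clades
# (E emu/cassowary, K kiwi, R rhea, S ostrich, T tinamou+moa)
# plus chicken as the sole outgroup clade O.
Casuarius_casuarius	E
Dromaius_novaehollandiae	E
Apteryx_hastii	K
Apteryx_mantelli	K
Apteryx_owenii	K
Apteryx_rowi	K
Rhea_americana	R
Rhea_pennata	R
Struthio_camelus	S
Anomalopteryx_didiformis	T
Crypturellus_cinnamomeus	T
Eudromia_elegans	T
Nothoprocta_perdicaria	T
Tinamus_guttatus	T
Gallus_gallus	O
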