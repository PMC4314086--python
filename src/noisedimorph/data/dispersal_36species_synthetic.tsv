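species	taxon	chromosome_system	dispersing_sex
Mus musculus	mammal	XY	male
Rattus norvegicus	mammal	XY	male
Ovis canadensis	mammal	XY	male
Canis lupus	mammal	XY	male
Ursus arctos	mammal	XY	male
Cervus elaphus	mammal	XY	male
Panthera leo	mammal	XY	male
Macaca mulatta	mammal	XY	male
Papio cynocephalus	mammal	XY	male
Halichoerus grypus	mammal	XY	male
Sciurus vulgaris	mammal	XY	male
Microtus agrestis	mammal	XY	male
Crocidura russula	mammal	XY	female
Ellobius lutescens	mammal	XO	male
Drosophila melanogaster	insect	XY	male
Ceratitis capitata	insect	XY	male
Musca domestica	insect	XY	male
Schistocerca gregaria	insect	XO	female
Chorthippus brunneus	insect	XO	female
Danaus plexippus	insect	ZW	female
Pieris napi	insect	ZW	female
Heliconius melpomene	insect	ZW	male
Bicyclus anynana	insect	ZW	male
Micropterix calthella	insect	ZO	male
Hepialus humuli	insect	ZO	male
Parus major	bird	ZW	female
Ficedula albicollis	bird	ZW	female
Hirundo rustica	bird	ZW	female
Passer domesticus	bird	ZW	female
Turdus merula	bird	ZW	female
Erithacus rubecula	bird	ZW	female
Sylvia atricapilla	bird	ZW	female
Larus argentatus	bird	ZW	female
Columba livia	bird	ZW	female
Taeniopygia guttata	bird	ZW	female
Gallus gallus	bird	ZW	female
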