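query_species	database	match_species	similarity
Rita rita	genbank	Rita rita	99
Rita rita	bold	Rita rita	100
Mystus bleekeri	genbank	Mystus bocourti	88
Mystus bleekeri	bold	NO_MATCH
Mystus cavasius	genbank	Mystus oculatus	89
Mystus cavasius	bold	NO_MATCH
Mystus vittatus	genbank	Mystus vittatus	99
Mystus vittatus	genbank	Mystus horai	99
Mystus vittatus	bold	Mystus vittatus	99.83
Mystus vittatus	bold	Mystus horai	99.64
Sperata aor	genbank	Sperata aor	100
Sperata aor	bold	Sperata aor	100
Hemibagrus menoda	genbank	Sperata aor	86
Hemibagrus menoda	bold	NO_MATCH
Bagarius bagarius	genbank	Bagarius bagarius	100
Bagarius bagarius	genbank	Bagarius yarrelli	100
Bagarius bagarius	genbank	Bagarius yarrelli	91
Bagarius bagarius	bold	Bagarius bagarius	100
Bagarius bagarius	bold	Bagarius yarrelli	100
Gagata cenia	genbank	Gagata cenia	99
Gagata cenia	bold	Gagata cenia	99.5
Gagata sexualis	genbank	Gagata sexualis	99
Gagata sexualis	bold	Gagata sexualis	99
Glyptothorax telchitta	genbank	Glyptothorax telchitta	93
Glyptothorax telchitta	bold	NO_MATCH
Glyptothorax striatus	genbank	Glyptothorax striatus	97
Glyptothorax striatus	bold	Glyptothorax striatus	97.6
Glyptothorax trilineatus	genbank	Glyptothorax trilineatus	96
Glyptothorax trilineatus	bold	NO_MATCH
Sisor rabdophorus	genbank	Sisor rabdophorus	100
Sisor rabdophorus	bold	Sisor rabdophorus	100
Ailia coila	genbank	Ailia coila	99
Ailia coila	bold	Ailia coila	99.67
Clupisoma garua	genbank	Laides hexanema	91
Clupisoma garua	bold	NO_MATCH
Eutropiichthys murius	genbank	Pangasius larnaudii	86
Eutropiichthys murius	bold	NO_MATCH
Eutropiichthys vacha	genbank	Laides hexanema	89
Eutropiichthys vacha	bold	NO_MATCH
Ompok bimaculatus	genbank	Ompok bimaculatus	99
Ompok bimaculatus	bold	Ompok bimaculatus	99.84
Ompok pabo	genbank	Ompok pabo	99
Ompok pabo	bold	Ompok pabo	99.33
Wallago attu	genbank	Wallago attu	100
Wallago attu	bold	Wallago attu	100
Clarias batrachus	genbank	Clarias batrachus	98
Clarias batrachus	genbank	Clarias batrachus	90
Clarias batrachus	bold	Clarias batrachus	98.64
Heteropneustes fossilis	genbank	Heteropneustes fossilis	100
Heteropneustes fossilis	bold	NO_MATCH
Erethistes pusillus	genbank	Erethistes pusillus	93
Erethistes pusillus	bold	NO_MATCH
Amblyceps apangi	genbank	Amblyceps apangi	95
Amblyceps apangi	genbank	Amblyceps apangi	88
Amblyceps apangi	bold	NO_MATCH
Olyra longicaudata	genbank	Amblyceps mucronatum	90
Olyra longicaudata	bold	NO_MATCH
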