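species	kind	accession
Mystus vittatus	conspecific_merge	FJ170791
Bagarius bagarius	conspecific_merge	DQ508069
Clarias batrachus	deep_conspecific_divergence	HQ654701
Amblyceps apangi	deep_conspecific_divergence	EU490873
Amblyceps apangi	deep_conspecific_divergence	DQ508066
Glyptothorax telchitta	deep_conspecific_divergence	DQ514362
Glyptothorax trilineatus	deep_conspecific_divergence	DQ508077
Erethistes pusillus	deep_conspecific_divergence	DQ508074
Erethistes pusillus	deep_conspecific_divergence	DQ508079
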