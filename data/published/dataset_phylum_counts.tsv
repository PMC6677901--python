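# Published taxonomic composition of the non-redundant (50% identity) MocR
# AAT-domain dataset: sequence counts per bacterial phylum.
phylum	count
Actinobacteria	248
Alphaproteobacteria	260
Bacteroidetes	57
Betaproteobacteria	143
Firmicutes	369
Gammaproteobacteria	254
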