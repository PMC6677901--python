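# Published phylum-by-cluster composition of the three MocR subgroups from
# K-means clustering: per-cluster size and per-phylum counts.
cluster	size	Actinobacteria	Alphaproteobacteria	Bacteroidetes	Betaproteobacteria	Gammaproteobacteria	Firmicutes
GabR	535	106	99	22	45	76	187
PtsJ	555	132	45	34	76	123	145
EnuR	242	10	116	1	23	55	37
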