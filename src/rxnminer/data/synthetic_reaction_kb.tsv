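# SYNTHETIC stand-in reaction knowledge base (substrate TAB product).
# Hand-written list of well-known 1:1 microbial substrate->product
# transformations for tests, examples and the synthetic corpus; it is NOT
# an export of any curated database.
gluconic acid	ethanol
glucose	gluconic acid
glucose	ethanol
lactose	lactate
pyruvate	lactate
pyruvate	acetaldehyde
acetaldehyde	ethanol
ethanol	acetate
glycerol	1,3-propanediol
fumarate	succinate
malate	fumarate
citrate	isocitrate
xylose	xylitol
sorbitol	fructose
glucose	fructose
tryptophan	indole
histidine	histamine
ornithine	putrescine
benzoate	catechol
naproxen nitrile	s-naproxen
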