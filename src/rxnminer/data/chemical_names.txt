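# Metabolite-style chemical name vocabulary for the synthetic corpus
# generator (plausible names only; the generator can extend the pool with
# CHEM_0001-style synthetic tokens).
glucose
fructose
galactose
sucrose
lactose
maltose
xylose
arabinose
ribose
sorbitol
mannitol
xylitol
glycerol
ethanol
methanol
butanol
propanol
acetone
acetaldehyde
acetate
lactate
pyruvate
citrate
isocitrate
malate
fumarate
succinate
oxaloacetate
glutamate
aspartate
alanine
serine
glycine
threonine
leucine
valine
proline
tryptophan
tyrosine
histidine
ornithine
putrescine
spermidine
histamine
indole
catechol
benzoate
phenol
toluene
naphthalene
vanillin
ferulate
choline
betaine
urea
urate
creatinine
inosine
adenosine
guanosine
thymidine
riboflavin
thiamine
biotin
folate
cobalamin
trehalose
cellobiose
chitin
butyrate
propionate
valerate
caproate
palmitate
stearate
oleate
linoleate
cholesterol
ergosterol
squalene
lycopene
carotene
menaquinone
ubiquinone
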