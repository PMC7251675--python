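# Functional-group terms; a mention with one of these within the
# configured token window is vetoed (the chemical is likely a fragment or
# moiety of a larger molecule, not a reaction participant).
methyl
ethyl
propyl
butyl
phenyl
benzyl
acetyl
hydroxyl
carboxyl
carbonyl
amino
nitro
sulfhydryl
thiol
aldehyde
ketone
ester
ether
amide
moiety
group
residue
substituent
side-chain
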