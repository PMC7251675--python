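# Reaction trigger keywords and phrases for the keyword-context labeling
# function.  Single words are matched with inflection tolerance (stem on a
# trailing -e, allow -s/-es/-d/-ed/-ing); multi-word entries are matched as
# phrases in the text between the two mentions.
reduce
oxidize
oxidise
transform
afford
convert
yield
hydrolyze
hydrolyse
metabolize
metabolise
dehydrogenate
decarboxylate
isomerize
isomerise
oxidized to
oxidised to
reduced to
converted to
converted into
conversion to
conversion of
transformed to
transformed into
transformation to
hydrolysis of
metabolized to
metabolised to
gives rise to
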