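# Chemical element names (English), used by the element-veto labeling
# function; matching is case-insensitive on the normalized mention surface.
hydrogen
helium
lithium
beryllium
boron
carbon
nitrogen
oxygen
fluorine
neon
sodium
magnesium
aluminium
aluminum
silicon
phosphorus
sulfur
sulphur
chlorine
argon
potassium
calcium
titanium
chromium
manganese
iron
cobalt
nickel
copper
zinc
arsenic
selenium
bromine
molybdenum
silver
cadmium
tin
iodine
platinum
gold
mercury
lead
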