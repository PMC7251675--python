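# Verb lexicon for the rule-based POS tagger.
# Base forms; the tagger also recognizes -s/-es/-ed/-d/-ing inflections.
be
is
are
was
were
been
being
has
have
had
can
could
may
might
will
would
should
yield
convert
produce
form
generate
give
afford
transform
reduce
oxidize
oxidise
hydrolyze
hydrolyse
catalyze
catalyse
metabolize
metabolise
degrade
synthesize
synthesise
dehydrogenate
decarboxylate
phosphorylate
methylate
acetylate
cleave
inhibit
activate
bind
react
release
consume
utilize
use
measure
detect
observe
report
show
suggest
indicate
demonstrate
obtain
isolate
identify
treat
administer
receive
add
incubate
grow
culture
express
encode
require
increase
decrease
accumulate
occur
result
lead
undergo
mediate
involve
contain
perform
study
investigate
determine
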