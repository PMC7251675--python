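"""Parse a PubTator block and enumerate ordered reaction candidates.

A sentence with n tagged chemicals yields n(n-1) ordered candidates: both
orders of every pair, because the substrate/product direction is part of
what the pipeline must decide.
"""

import io

from rxnminer import extract_candidates, read_pubtator
from rxnminer.corpus_io import RuleAnnotator, align_mentions, annotate

BLOCK = """\
555|t|Sugar conversion study.
555|a|Xylose is converted into xylitol in the absence of glucose.
555\t24\t30\tXylose\tChemical\t
555\t49\t56\txylitol\tChemical\t
555\t75\t82\tglucose\tChemical\t

"""

documents, mentions = read_pubtator(io.StringIO(BLOCK))
doc = documents[0]
annotate(doc, RuleAnnotator())
aligned = align_mentions(doc, mentions)
candidates = extract_candidates(doc, aligned)

print(f"{len(aligned)} chemical mentions -> {len(candidates)} ordered candidates")
for c in candidates:
    print(f"  {c.arg1.surface:>8s} -> {c.arg2.surface}")
print("Three co-occurring chemicals give 3*2 = 6 ordered pairs; only one")
print("of them (Xylose -> xylitol) is the reaction the sentence asserts.")
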