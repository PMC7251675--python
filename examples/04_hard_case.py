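"""The co-occurring decoy-substrate hard case.

A sentence like "Only D-cysteine but not L-cysteine was converted by
D-CDes to pyruvate, H2S, and NH3" defeats co-occurrence rules: both
cysteine stereoisomers look like substrates, so a predictor that accepts
every substrate->product pair is wrong on exactly half of them.
"""

from rxnminer import adversarial_fixture, evaluate, extract_candidates
from rxnminer.synthetic_corpus import gold_labels_for_candidates, materialize

text, gold_rel = adversarial_fixture()
documents, mentions = materialize(text)
doc = documents[0]
candidates = extract_candidates(doc, mentions)
gold = gold_labels_for_candidates(gold_rel, candidates)

print(doc.abstract)
print(f"\n{len(mentions)} chemical mentions -> {len(candidates)} candidates, "
      f"{sum(v == 1 for v in gold.values())} true reactions")

substrates = {m.span for m in mentions if "cysteine" in m.surface}
products = {m.span for m in mentions if "cysteine" not in m.surface}
preds = {c.candidate_id: (1 if c.arg1.span in substrates
                          and c.arg2.span in products else -1)
         for c in candidates}
report = evaluate(preds, gold)
print(f"\npair-enumerating predictor: {sum(v == 1 for v in preds.values())} "
      f"extractions, precision {report.precision:.2f}, recall {report.recall:.2f}")
print("Half of the extractions pair the decoy substrate with the products,")
print("so precision is exactly 0.50 even though recall is perfect.")
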