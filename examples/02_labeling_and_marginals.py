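"""Apply labeling functions to a synthetic corpus and fit the label model.

Prints the per-LF coverage/overlaps/conflicts diagnostics used to iterate
on rule design, then the training marginals produced by the generative
model (per-candidate probabilities of a true reaction).
"""

import numpy as np

from rxnminer import (
    DEFAULT_LFS,
    GeneratorConfig,
    LabelMatrix,
    apply_lfs,
    compute_lf_stats,
    extract_candidates,
    fit_generative,
    generate_corpus,
    majority_vote,
)
from rxnminer.synthetic_corpus import gold_labels_for_candidates, materialize

config = GeneratorConfig(n_docs=100, seed=0)  # ~5% positive candidates
text, gold = generate_corpus(config)
documents, mentions = materialize(text)
candidates = []
for doc in documents:
    candidates.extend(extract_candidates(doc, mentions))

L = LabelMatrix(apply_lfs(candidates, documents),
                [lf.name for lf in DEFAULT_LFS],
                [c.candidate_id for c in candidates])

stats = compute_lf_stats(L)
print(f"{'labeling function':24s} coverage overlaps conflicts")
for j, name in enumerate(stats.lf_names):
    print(f"{name:24s} {stats.coverage[j]:8.4f} {stats.overlaps[j]:8.4f} "
          f"{stats.conflicts[j]:9.4f}")

preds, coverage = majority_vote(L)
print(f"\nmajority vote covers {coverage:.2f} of candidates "
      "(ties and all-abstain rows abstain)")

params, marginals = fit_generative(L, prior=0.5, seed=0)
labels = gold_labels_for_candidates(gold, candidates)
is_pos = np.array([labels[c.candidate_id] == 1 for c in candidates])
print(f"mean marginal on gold positives: {marginals[is_pos].mean():.3f}")
print(f"mean marginal on gold negatives: {marginals[~is_pos].mean():.3f}")
print("Marginals above/below the 0.5 prior separate likely reactions from")
print("vetoed pairs; they become soft targets for the discriminative model.")
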