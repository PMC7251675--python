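"""Shared fixtures: all corpora are generated programmatically at test time."""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pytest

from rxnminer.candidates import Candidate, extract_candidates
from rxnminer.corpus_io import (
    Document,
    EntityMention,
    RuleAnnotator,
    align_mentions,
    annotate,
)
from rxnminer.label_model import LabelMatrix
from rxnminer.labeling_functions import DEFAULT_LFS, apply_lfs
from rxnminer.resources import Resources
from rxnminer.synthetic_corpus import (
    GeneratorConfig,
    generate_corpus,
    gold_labels_for_candidates,
    materialize,
)


@pytest.fixture(scope="session")
def annotator() -> RuleAnnotator:
    return RuleAnnotator()


@pytest.fixture(scope="session")
def resources() -> Resources:
    return Resources.default()


def make_document(sentence_text: str, chem_surfaces: list[str],
                  annotator: RuleAnnotator | None = None,
                  title: str = "Study.") -> tuple[Document, list[EntityMention]]:
    """One-document corpus with mentions located by surface search.

    Repeated surfaces are resolved left to right, so a name may appear
    more than once in ``chem_surfaces``.
    """
    doc = Document(doc_id="1", title=title, abstract=sentence_text)
    annotate(doc, annotator or RuleAnnotator())
    mentions = []
    pos = len(title) + 1
    search_from: dict[str, int] = {}
    for surf in chem_surfaces:
        start = doc.text.index(surf, search_from.get(surf, pos))
        search_from[surf] = start + len(surf)
        mentions.append(EntityMention(doc_id="1", span=(start, start + len(surf)),
                                      surface=surf))
    return doc, align_mentions(doc, mentions)


def candidate_pair(doc: Document, mentions, i: int, j: int) -> Candidate:
    """The (mentions[i] -> mentions[j]) candidate, by mention list position."""
    cands = extract_candidates(doc, mentions)
    for c in cands:
        if c.arg1.span == mentions[i].span and c.arg2.span == mentions[j].span:
            return c
    raise LookupError("candidate not found")


@dataclass
class CorpusBundle:
    documents: list
    mentions: list
    candidates: list
    gold: dict  # candidate_id -> {+1, -1}
    matrix: LabelMatrix


@pytest.fixture(scope="session")
def default_corpus(resources) -> CorpusBundle:
    """The default synthetic corpus with LFs applied (seeded, 200 docs)."""
    config = GeneratorConfig(n_docs=200, seed=0)
    text, gold_rel = generate_corpus(config)
    documents, aligned = materialize(text)
    candidates = []
    for doc in documents:
        candidates.extend(extract_candidates(doc, aligned))
    gold = gold_labels_for_candidates(gold_rel, candidates)
    L = LabelMatrix(
        data=apply_lfs(candidates, documents, resources=resources),
        lf_names=[lf.name for lf in DEFAULT_LFS],
        candidate_ids=[c.candidate_id for c in candidates])
    return CorpusBundle(documents=documents, mentions=aligned,
                        candidates=candidates, gold=gold, matrix=L)


@pytest.fixture()
def tiny_pubtator() -> str:
    return ("123|t|Glucose study.\n"
            "123|a|Glucose yields ethanol.\n"
            "123\t15\t22\tGlucose\tChemical\tMESH:D005947\n"
            "\n")


def read_corpus(text: str):
    from rxnminer.corpus_io import read_pubtator

    return read_pubtator(io.StringIO(text))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
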