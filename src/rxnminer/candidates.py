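"""Candidate generation: ordered pairs of co-occurring chemical mentions.

A candidate reaction is an ordered pair of distinct chemical mentions in
the same sentence — arg1 the putative substrate, arg2 the putative
product.  A sentence with n chemical mentions therefore yields n(n-1)
candidates (both orders of every unordered pair).  No filtering happens
here by design: the definition is maximally high-recall and every veto
lives in a labeling function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from .corpus_io import Document, EntityMention


@dataclass(frozen=True)
class Candidate:
    candidate_id: str
    doc_id: str
    sentence_index: int
    arg1: EntityMention  # putative substrate
    arg2: EntityMention  # putative product


def _candidate_id(doc_id: str, sentence_index: int,
                  arg1: EntityMention, arg2: EntityMention) -> str:
    return (f"{doc_id}:{sentence_index}:"
            f"{arg1.span[0]}-{arg1.span[1]}:{arg2.span[0]}-{arg2.span[1]}")


def extract_candidates(document: Document,
                       mentions: Iterable[EntityMention]) -> list[Candidate]:
    """All ordered pairs of distinct chemical mentions per sentence.

    Mentions must already be aligned (``sentence_index`` set).  Distinct
    means distinct spans: two mentions with the same surface text at
    different positions still pair.  Output order is deterministic — by
    sentence, then arg1 start, then arg2 start.
    """
    by_sentence: dict[int, list[EntityMention]] = {}
    for men in mentions:
        if men.doc_id != document.doc_id or men.sentence_index is None:
            continue
        by_sentence.setdefault(men.sentence_index, []).append(men)

    out: list[Candidate] = []
    for sent_idx in sorted(by_sentence):
        sent_mentions = sorted(by_sentence[sent_idx], key=lambda m: m.span)
        for m1 in sent_mentions:
            for m2 in sent_mentions:
                if m1.span == m2.span:
                    continue
                out.append(Candidate(
                    candidate_id=_candidate_id(document.doc_id, sent_idx, m1, m2),
                    doc_id=document.doc_id,
                    sentence_index=sent_idx,
                    arg1=m1,
                    arg2=m2,
                ))
    return out


def corpus_candidate_stats(documents: list[Document],
                           candidates: list[Candidate]) -> dict[str, float]:
    """Corpus-level candidate counts.

    Returns abstracts, candidates, mean candidates per abstract, and the
    number/proportion of documents with at least one candidate.
    """
    n_docs = len(documents)
    docs_with = len({c.doc_id for c in candidates})
    return {
        "abstracts": n_docs,
        "candidates": len(candidates),
        "mean_candidates_per_abstract": len(candidates) / n_docs if n_docs else 0.0,
        "docs_with_candidates": docs_with,
        "prop_docs_with_candidates": docs_with / n_docs if n_docs else 0.0,
    }


_TSV_HEADER = ("candidate_id\tpmid\tsentence_index\targ1_text\targ1_start\targ1_end\t"
               "arg2_text\targ2_start\targ2_end\n")


def write_candidates_tsv(candidates: list[Candidate], stream: TextIO) -> None:
    stream.write(_TSV_HEADER)
    for c in candidates:
        stream.write(
            f"{c.candidate_id}\t{c.doc_id}\t{c.sentence_index}\t"
            f"{c.arg1.surface}\t{c.arg1.span[0]}\t{c.arg1.span[1]}\t"
            f"{c.arg2.surface}\t{c.arg2.span[0]}\t{c.arg2.span[1]}\n"
        )


def read_candidates_tsv(stream: TextIO | Iterable[str]) -> list[Candidate]:
    out = []
    for i, line in enumerate(stream):
        line = line.rstrip("\n")
        if not line or (i == 0 and line.startswith("candidate_id\t")):
            continue
        (cid, pmid, sidx, a1t, a1s, a1e, a2t, a2s, a2e) = line.split("\t")
        arg1 = EntityMention(doc_id=pmid, span=(int(a1s), int(a1e)), surface=a1t,
                             sentence_index=int(sidx))
        arg2 = EntityMention(doc_id=pmid, span=(int(a2s), int(a2e)), surface=a2t,
                             sentence_index=int(sidx))
        out.append(Candidate(candidate_id=cid, doc_id=pmid, sentence_index=int(sidx),
                             arg1=arg1, arg2=arg2))
    return out
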