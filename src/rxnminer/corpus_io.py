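"""PubTator corpus reading/writing and linguistic annotation.

A PubTator block looks like::

    1234|t|Glucose study.
    1234|a|Glucose yields ethanol.
    1234<TAB>15<TAB>22<TAB>Glucose<TAB>Chemical<TAB>MESH:D005947

Character offsets are global to ``title + " " + abstract`` (the PubTator
convention) and all spans here are 0-based half-open intervals.

Linguistic annotation (sentences, tokens, POS) is a pluggable contract:
any callable mapping a document's text to a list of :class:`Sentence`
objects can be used.  The package ships :class:`RuleAnnotator`, a
deterministic splitter/tokenizer/tagger that needs no model downloads,
and :class:`CachedAnnotator`, which replays parses exported from any
external parser via a TSV cache.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, TextIO

from .resources import load_lexicon

logger = logging.getLogger(__name__)

Span = tuple[int, int]


class PubTatorParseError(ValueError):
    """Raised for a malformed title/abstract header line."""


class AnnotationError(RuntimeError):
    """Raised when an annotator fails on a document."""


@dataclass(frozen=True)
class Token:
    text: str
    span: Span
    pos: str  # coarse tag; at minimum VERB vs non-VERB is distinguished
    lemma: str


@dataclass(frozen=True)
class Sentence:
    index: int
    span: Span
    tokens: tuple[Token, ...] = ()


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def text(self) -> str:
        if self.abstract:
            return self.title + " " + self.abstract
        return self.title


@dataclass(frozen=True)
class EntityMention:
    doc_id: str
    span: Span
    surface: str
    entity_type: str = "Chemical"
    normalized_id: str | None = None
    sentence_index: int | None = None


Annotator = Callable[[str], list[Sentence]]

_HEADER_RE = re.compile(r"^([^|]+)\|([ta])\|(.*)$")


def read_pubtator(stream: TextIO | Iterable[str]) -> tuple[list[Document], list[EntityMention]]:
    """Parse a PubTator stream into documents and Chemical mentions.

    Non-Chemical annotations are skipped; annotations whose text does not
    match the document substring at the stated offsets, or that reference
    an unknown pmid, are dropped with a warning.  Overlapping Chemical
    annotations within a document are resolved by keeping the longest
    mention (ties: earliest start).
    """
    docs: dict[str, Document] = {}
    raw_mentions: dict[str, list[EntityMention]] = {}
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    order: list[str] = []

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if "\t" in line:
            parts = line.split("\t")
            if len(parts) < 5:
                logger.warning("line %d: short annotation line dropped", lineno)
                continue
            pmid, start_s, end_s, text, etype = parts[:5]
            norm_id = parts[5] if len(parts) > 5 and parts[5] else None
            if pmid not in titles:
                logger.warning("line %d: annotation for unknown pmid %r dropped", lineno, pmid)
                continue
            if etype != "Chemical":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("line %d: non-integer offsets dropped", lineno)
                continue
            raw_mentions.setdefault(pmid, []).append(
                EntityMention(doc_id=pmid, span=(start, end), surface=text,
                              entity_type=etype, normalized_id=norm_id)
            )
            continue
        m = _HEADER_RE.match(line)
        if m is None:
            raise PubTatorParseError(f"line {lineno}: malformed header line: {line!r}")
        pmid, kind, content = m.groups()
        if kind == "t":
            titles[pmid] = content
            if pmid not in order:
                order.append(pmid)
        else:
            abstracts[pmid] = content

    documents = []
    mentions: list[EntityMention] = []
    for pmid in order:
        doc = Document(doc_id=pmid, title=titles[pmid], abstract=abstracts.get(pmid, ""))
        documents.append(doc)
        valid = []
        for men in raw_mentions.get(pmid, []):
            start, end = men.span
            if not (0 <= start < end <= len(doc.text)) or doc.text[start:end] != men.surface:
                logger.warning(
                    "doc %s: mention %r at [%d,%d) does not match text; dropped",
                    pmid, men.surface, start, end,
                )
                continue
            valid.append(men)
        mentions.extend(_resolve_overlaps(valid))
    return documents, mentions


def _resolve_overlaps(mentions: list[EntityMention]) -> list[EntityMention]:
    """Keep the longest mention per overlapping region; ties by earliest start."""
    chosen: list[EntityMention] = []
    # longest first, then earliest start, then offset order for stability
    for men in sorted(mentions, key=lambda m: (-(m.span[1] - m.span[0]), m.span[0])):
        if any(men.span[0] < kept.span[1] and kept.span[0] < men.span[1] for kept in chosen):
            logger.warning("doc %s: overlapping mention %r dropped", men.doc_id, men.surface)
            continue
        chosen.append(men)
    return sorted(chosen, key=lambda m: m.span)


def write_pubtator(documents: list[Document], mentions: list[EntityMention],
                   stream: TextIO) -> None:
    """Write documents + mentions back out in PubTator format."""
    by_doc: dict[str, list[EntityMention]] = {}
    for men in mentions:
        by_doc.setdefault(men.doc_id, []).append(men)
    for doc in documents:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for men in sorted(by_doc.get(doc.doc_id, []), key=lambda m: m.span):
            norm = men.normalized_id or ""
            stream.write(
                f"{men.doc_id}\t{men.span[0]}\t{men.span[1]}\t{men.surface}\t"
                f"{men.entity_type}\t{norm}\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------------
# Rule-based fallback annotator


_SENT_BOUNDARY = re.compile(r"[.!?]+(?=\s)")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")
_VERB_SUFFIX_STRIP = ("ing", "ed", "es", "s", "d")


class RuleAnnotator:
    """Deterministic sentence splitter, tokenizer and POS tagger.

    Sentences break after terminal punctuation followed by whitespace.
    Tokens are alphanumeric runs (hyphen/apostrophe-joined) or single
    punctuation characters.  POS tagging is lexicon-based: a token whose
    lowercased form (or that form with a common inflectional suffix
    stripped) is in the verb lexicon is tagged VERB; punctuation is
    PUNCT; everything else WORD.
    """

    def __init__(self, verb_lexicon: frozenset[str] | None = None):
        self.verbs = verb_lexicon if verb_lexicon is not None else load_lexicon("verbs")

    def tag(self, token_text: str) -> str:
        low = token_text.lower()
        if not any(ch.isalnum() for ch in low):
            return "PUNCT"
        if low in self.verbs:
            return "VERB"
        for suf in _VERB_SUFFIX_STRIP:
            if low.endswith(suf) and len(low) > len(suf) + 1:
                stem = low[: -len(suf)]
                if stem in self.verbs or stem + "e" in self.verbs:
                    return "VERB"
        return "WORD"

    def __call__(self, text: str) -> list[Sentence]:
        boundaries = [m.end() for m in _SENT_BOUNDARY.finditer(text)]
        starts = [0] + boundaries
        ends = boundaries + [len(text)]
        sentences = []
        index = 0
        for raw_start, raw_end in zip(starts, ends):
            seg = text[raw_start:raw_end]
            stripped = seg.strip()
            if not stripped:
                continue
            start = raw_start + (len(seg) - len(seg.lstrip()))
            end = start + len(stripped)
            tokens = tuple(
                Token(
                    text=m.group(0),
                    span=(start + m.start(), start + m.end()),
                    pos=self.tag(m.group(0)),
                    lemma=m.group(0).lower(),
                )
                for m in _TOKEN_RE.finditer(stripped)
            )
            sentences.append(Sentence(index=index, span=(start, end), tokens=tokens))
            index += 1
        return sentences


def annotate(document: Document, annotator: Annotator | None = None) -> Document:
    """Populate ``document.sentences`` using the given annotator.

    Deterministic for a fixed annotator; raises :class:`AnnotationError`
    carrying the doc_id if the annotator fails.
    """
    if annotator is None:
        annotator = RuleAnnotator()
    if not document.text:
        raise AnnotationError(f"doc {document.doc_id}: empty text")
    try:
        document.sentences = annotator(document.text)
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise AnnotationError(f"doc {document.doc_id}: annotator failed: {exc}") from exc
    return document


def align_mentions(document: Document, mentions: list[EntityMention]) -> list[EntityMention]:
    """Assign each mention the sentence containing its span.

    Mentions crossing a sentence boundary (contained by no sentence) are
    dropped with a warning; drops are never fatal.
    """
    aligned = []
    for men in mentions:
        if men.doc_id != document.doc_id:
            continue
        hit = None
        for sent in document.sentences:
            if sent.span[0] <= men.span[0] and men.span[1] <= sent.span[1]:
                hit = sent.index
                break
        if hit is None:
            logger.warning("doc %s: mention %r crosses sentence boundary; dropped",
                           document.doc_id, men.surface)
            continue
        aligned.append(replace(men, sentence_index=hit))
    return aligned


# ---------------------------------------------------------------------------
# Annotator cache (inject parses from an external parser)


def write_annotation_cache(documents: list[Document], stream: TextIO) -> None:
    """TSV cache: doc_id, sentence index, sentence span, token spans, POS tags.

    Token columns are comma-separated ``start:end`` and tag lists aligned
    positionally.
    """
    stream.write("doc_id\tsentence_index\tstart\tend\ttoken_spans\tpos_tags\n")
    for doc in documents:
        for sent in doc.sentences:
            spans = ",".join(f"{t.span[0]}:{t.span[1]}" for t in sent.tokens)
            tags = ",".join(t.pos for t in sent.tokens)
            stream.write(
                f"{doc.doc_id}\t{sent.index}\t{sent.span[0]}\t{sent.span[1]}\t{spans}\t{tags}\n"
            )


class CachedAnnotator:
    """Replays sentence/token/POS annotations from a cache TSV for one corpus.

    Construct with the cache stream, then call ``annotate_document(doc)``;
    the plain ``Annotator`` contract is supported via ``for_document``.
    """

    def __init__(self, stream: TextIO | Iterable[str]):
        self._rows: dict[str, list[tuple[int, Span, list[Span], list[str]]]] = {}
        header_skipped = False
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            if not header_skipped:
                header_skipped = True
                if line.startswith("doc_id\t"):
                    continue
            doc_id, idx, start, end, spans_s, tags_s = line.split("\t")
            spans = [tuple(map(int, p.split(":"))) for p in spans_s.split(",")] if spans_s else []
            tags = tags_s.split(",") if tags_s else []
            self._rows.setdefault(doc_id, []).append(
                (int(idx), (int(start), int(end)), spans, tags)  # type: ignore[arg-type]
            )

    def annotate_document(self, document: Document) -> Document:
        rows = self._rows.get(document.doc_id)
        if rows is None:
            raise AnnotationError(f"doc {document.doc_id}: not present in annotation cache")
        text = document.text
        sentences = []
        for idx, span, tok_spans, tags in sorted(rows):
            tokens = tuple(
                Token(text=text[s:e], span=(s, e), pos=tag, lemma=text[s:e].lower())
                for (s, e), tag in zip(tok_spans, tags)
            )
            sentences.append(Sentence(index=idx, span=span, tokens=tokens))
        document.sentences = sentences
        return document
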