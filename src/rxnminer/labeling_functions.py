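"""Unipolar labeling functions for candidate chemical reactions.

Each labeling function (LF) maps a candidate, in sentence context, to one
of three labels: TRUE (+1), FALSE (-1) or ABSTAIN (0).  LFs here are
*unipolar*: a positive LF only ever emits TRUE or ABSTAIN, a negative LF
only FALSE or ABSTAIN.  Unipolarity keeps weak positive evidence from
being drowned by the many generic negative rules under heavy class
imbalance, and it is enforced at runtime.

"Between the two mentions" always means textual order — strictly between
the earlier mention's end and the later mention's start — regardless of
which mention is arg1.  A positive keyword between a reversed pair can
therefore conflict with the argument-order veto; such conflicts are real
signal and are surfaced by the label-matrix diagnostics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .candidates import Candidate
from .corpus_io import Document, Sentence, Token
from .resources import Resources, normalize_chemical

logger = logging.getLogger(__name__)

TRUE, FALSE, ABSTAIN = 1, -1, 0

POSITIVE = "positive"
NEGATIVE = "negative"


class PolarityViolation(RuntimeError):
    """A unipolar LF emitted the label its polarity forbids."""


@dataclass(frozen=True)
class LFContext:
    """Sentence-side view of a candidate, precomputed once per candidate."""

    sentence: Sentence
    arg1_tokens: tuple[int, int]  # token index range [start, end) of arg1
    arg2_tokens: tuple[int, int]
    between_tokens: tuple[Token, ...]  # strictly between, textual order

    @property
    def reversed_order(self) -> bool:
        return self.arg2_tokens[0] < self.arg1_tokens[0]


Rule = Callable[[Candidate, LFContext, Resources], int]


@dataclass(frozen=True)
class LabelingFunction:
    name: str
    polarity: str  # POSITIVE or NEGATIVE
    rule: Rule

    def __call__(self, cand: Candidate, ctx: LFContext, res: Resources) -> int:
        label = self.rule(cand, ctx, res)
        if label not in (TRUE, FALSE, ABSTAIN):
            raise PolarityViolation(f"{self.name}: invalid label {label!r}")
        if self.polarity == POSITIVE and label == FALSE:
            raise PolarityViolation(f"{self.name} is positive but emitted FALSE")
        if self.polarity == NEGATIVE and label == TRUE:
            raise PolarityViolation(f"{self.name} is negative but emitted TRUE")
        return label


def _token_range(sentence: Sentence, span: tuple[int, int]) -> tuple[int, int]:
    """Token index range [i, j) of tokens overlapping the character span."""
    idx = [i for i, t in enumerate(sentence.tokens)
           if t.span[0] < span[1] and span[0] < t.span[1]]
    if not idx:
        return (0, 0)
    return (idx[0], idx[-1] + 1)


def build_context(cand: Candidate, document: Document) -> LFContext:
    sentence = document.sentences[cand.sentence_index]
    r1 = _token_range(sentence, cand.arg1.span)
    r2 = _token_range(sentence, cand.arg2.span)
    first, second = (r1, r2) if r1[0] <= r2[0] else (r2, r1)
    between = sentence.tokens[first[1]:second[0]]
    return LFContext(sentence=sentence, arg1_tokens=r1, arg2_tokens=r2,
                     between_tokens=tuple(between))


# ---------------------------------------------------------------------------
# Keyword matching helpers

_INFLECTIONS = ("", "e", "s", "es", "d", "ed", "ing")


def _stem(entry: str) -> str:
    return entry[:-1] if entry.endswith("e") else entry


def _word_matches(token_lemma: str, entry: str) -> bool:
    stem = _stem(entry)
    return token_lemma.startswith(stem) and token_lemma[len(stem):] in _INFLECTIONS


def _keyword_between(ctx: LFContext, keywords: Iterable[str]) -> bool:
    between_text = " ".join(t.lemma for t in ctx.between_tokens)
    for entry in keywords:
        if " " in entry:
            if re.search(rf"\b{re.escape(entry)}\b", between_text):
                return True
        else:
            if any(_word_matches(t.lemma, entry) for t in ctx.between_tokens):
                return True
    return False


# ---------------------------------------------------------------------------
# The named labeling functions


def lf_keyword_context(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """TRUE if a reaction keyword (reduce, oxidize, transform, afford, ...)
    or trigger phrase occurs strictly between the two mentions."""
    return TRUE if _keyword_between(ctx, res.lexicons.reaction_keywords) else ABSTAIN


def lf_sep_verb(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """TRUE if at least one VERB-tagged token separates the mentions."""
    return TRUE if any(t.pos == "VERB" for t in ctx.between_tokens) else ABSTAIN


def lf_argument_order(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if the putative product appears before the putative substrate."""
    return FALSE if cand.arg2.span[0] < cand.arg1.span[0] else ABSTAIN


_MIN_ASE_LEN = 5  # avoids "base", "case" and other short -ase tokens


def lf_followed_ase(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if the token immediately after either mention ends with "ase"
    (case-insensitive, token length >= 5) — the chemical is likely an
    enzyme-name modifier, not a reaction participant."""
    for rng in (ctx.arg1_tokens, ctx.arg2_tokens):
        nxt = rng[1]
        if nxt < len(ctx.sentence.tokens):
            lemma = ctx.sentence.tokens[nxt].lemma
            if len(lemma) >= _MIN_ASE_LEN and lemma.endswith("ase"):
                return FALSE
    return ABSTAIN


def lf_sep_or(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if the word "or" lies strictly between the mentions (the
    chemicals are alternatives, not substrate and product)."""
    return FALSE if any(t.lemma == "or" for t in ctx.between_tokens) else ABSTAIN


def lf_kb_match(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """TRUE if the ordered (substrate, product) surface pair is already in
    the reaction knowledge base (case-insensitive exact match)."""
    pair = (normalize_chemical(cand.arg1.surface), normalize_chemical(cand.arg2.surface))
    return TRUE if pair in res.kb else ABSTAIN


def lf_chemical_elements(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if either mention is a bare chemical element name."""
    for men in (cand.arg1, cand.arg2):
        if normalize_chemical(men.surface) in res.lexicons.elements:
            return FALSE
    return ABSTAIN


def lf_group(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if a functional-group term occurs within ``res.group_window``
    tokens of either mention."""
    tokens = ctx.sentence.tokens
    w = res.group_window
    for rng in (ctx.arg1_tokens, ctx.arg2_tokens):
        lo = max(0, rng[0] - w)
        hi = min(len(tokens), rng[1] + w)
        for i in range(lo, hi):
            if rng[0] <= i < rng[1]:
                continue
            if tokens[i].lemma in res.lexicons.functional_groups:
                return FALSE
    return ABSTAIN


def lf_treatment(cand: Candidate, ctx: LFContext, res: Resources) -> int:
    """FALSE if the sentence mentions clinical-trial / treatment vocabulary
    (sentence-scoped: terms elsewhere in the abstract do not veto)."""
    for tok in ctx.sentence.tokens:
        if tok.lemma in res.lexicons.treatment_terms:
            return FALSE
    return ABSTAIN


DEFAULT_LFS: tuple[LabelingFunction, ...] = (
    LabelingFunction("lf_keyword_context", POSITIVE, lf_keyword_context),
    LabelingFunction("lf_sep_verb", POSITIVE, lf_sep_verb),
    LabelingFunction("lf_kb_match", POSITIVE, lf_kb_match),
    LabelingFunction("lf_argument_order", NEGATIVE, lf_argument_order),
    LabelingFunction("lf_followed_ase", NEGATIVE, lf_followed_ase),
    LabelingFunction("lf_sep_or", NEGATIVE, lf_sep_or),
    LabelingFunction("lf_chemical_elements", NEGATIVE, lf_chemical_elements),
    LabelingFunction("lf_group", NEGATIVE, lf_group),
    LabelingFunction("lf_treatment", NEGATIVE, lf_treatment),
)


class LFRegistry:
    """Name -> LabelingFunction registry; extensible with user-defined LFs."""

    def __init__(self, lfs: Iterable[LabelingFunction] = DEFAULT_LFS):
        self._lfs: dict[str, LabelingFunction] = {}
        for lf in lfs:
            self.register(lf)

    def register(self, lf: LabelingFunction) -> None:
        if lf.polarity not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown polarity {lf.polarity!r}")
        self._lfs[lf.name] = lf

    def get(self, name: str) -> LabelingFunction:
        return self._lfs[name]

    def select(self, names: Sequence[str] | None = None) -> list[LabelingFunction]:
        if names is None:
            return list(self._lfs.values())
        return [self._lfs[n] for n in names]

    def __iter__(self):
        return iter(self._lfs.values())

    def __len__(self) -> int:
        return len(self._lfs)


def apply_lfs(candidates: Sequence[Candidate],
              documents: Iterable[Document],
              lfs: Sequence[LabelingFunction] | None = None,
              resources: Resources | None = None,
              strict: bool = True) -> "np.ndarray":
    """Apply every LF to every candidate, producing an (N, J) array over
    {-1, 0, +1}.

    An LF raising an arbitrary internal error records ABSTAIN for that
    entry and logs — one buggy rule must not kill a corpus run.  Polarity
    violations are contract bugs: in strict mode (default) they raise,
    otherwise they are recorded as ABSTAIN and logged.
    """
    if lfs is None:
        lfs = list(DEFAULT_LFS)
    if resources is None:
        resources = Resources.default()
    doc_map = {d.doc_id: d for d in documents}
    L = np.zeros((len(candidates), len(lfs)), dtype=np.int8)
    for i, cand in enumerate(candidates):
        ctx = build_context(cand, doc_map[cand.doc_id])
        for j, lf in enumerate(lfs):
            try:
                L[i, j] = lf(cand, ctx, resources)
            except PolarityViolation:
                if strict:
                    raise
                logger.error("polarity violation in %s on %s; recording ABSTAIN",
                             lf.name, cand.candidate_id)
            except Exception:  # noqa: BLE001 - LF bugs must not kill the run
                logger.exception("LF %s failed on %s; recording ABSTAIN",
                                 lf.name, cand.candidate_id)
    return L
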