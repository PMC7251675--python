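"""Packaged lexicons and the substrate->product reaction knowledge base.

Lexicon files are one term per line, UTF-8, with ``#`` comments; all
entries are normalized to lowercase.  The KB file is a two-column TSV
(substrate TAB product).  Users point the loaders at their own files to
override any default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, TextIO

_WS = re.compile(r"\s+")


def _normalize(term: str) -> str:
    return _WS.sub(" ", term.strip().lower())


def _iter_lines(source: str | Path | TextIO | Iterable[str]):
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def load_lexicon(name_or_path: str | Path) -> frozenset[str]:
    """Load a lexicon by packaged name (e.g. ``"elements"``) or file path."""
    if isinstance(name_or_path, str) and not Path(name_or_path).exists():
        ref = importlib_resources.files("rxnminer.data") / f"{name_or_path}.txt"
        text = ref.read_text(encoding="utf-8").splitlines()
    else:
        text = list(_iter_lines(name_or_path))
    terms = set()
    for line in text:
        line = line.split("#", 1)[0].strip()
        if line:
            terms.add(_normalize(line))
    if not terms:
        raise ValueError(f"lexicon {name_or_path!r} is empty")
    return frozenset(terms)


@dataclass(frozen=True)
class Lexicons:
    """The term lists the rule-based labeling functions consult."""

    reaction_keywords: frozenset[str]
    elements: frozenset[str]
    functional_groups: frozenset[str]
    treatment_terms: frozenset[str]

    @classmethod
    def default(cls) -> "Lexicons":
        return cls(
            reaction_keywords=load_lexicon("reaction_keywords"),
            elements=load_lexicon("elements"),
            functional_groups=load_lexicon("functional_groups"),
            treatment_terms=load_lexicon("treatment_terms"),
        )


_EXCLUDED_KB_NAMES = frozenset({
    "water", "h2o", "hydrogen", "h2", "h+", "proton", "h", "hydron",
})


@dataclass(frozen=True)
class ReactionKB:
    """Curated (substrate, product) name pairs for distant supervision.

    Pairs are expected to be 1:1 substrate-product transformations with
    proton donors/acceptors, water and hydrogen already filtered out;
    :meth:`preprocess_pairs` applies those filters to a raw pair table.
    """

    pairs: frozenset[tuple[str, str]]
    provenance: str = "unspecified"

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (_normalize(a), _normalize(b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    @staticmethod
    def preprocess_pairs(raw_pairs: Iterable[tuple[str, str]]) -> frozenset[tuple[str, str]]:
        """Normalize and drop pairs involving water/hydrogen/proton carriers."""
        kept = set()
        for sub, prod in raw_pairs:
            sub_n, prod_n = _normalize(sub), _normalize(prod)
            if not sub_n or not prod_n or sub_n == prod_n:
                continue
            if sub_n in _EXCLUDED_KB_NAMES or prod_n in _EXCLUDED_KB_NAMES:
                continue
            kept.add((sub_n, prod_n))
        return frozenset(kept)

    @classmethod
    def from_tsv(cls, source: str | Path | TextIO | Iterable[str],
                 provenance: str = "file", preprocess: bool = True) -> "ReactionKB":
        raw = []
        for line in _iter_lines(source):
            line = line.split("#", 1)[0].rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            raw.append((parts[0], parts[1]))
        pairs = cls.preprocess_pairs(raw) if preprocess else frozenset(
            (_normalize(a), _normalize(b)) for a, b in raw
        )
        return cls(pairs=pairs, provenance=provenance)

    @classmethod
    def default(cls) -> "ReactionKB":
        """The packaged synthetic stand-in KB (see synthetic_reaction_kb.tsv)."""
        ref = importlib_resources.files("rxnminer.data") / "synthetic_reaction_kb.tsv"
        return cls.from_tsv(ref.read_text(encoding="utf-8").splitlines(),
                            provenance="synthetic")


@dataclass(frozen=True)
class Resources:
    """Bundle of everything labeling functions may consult."""

    lexicons: Lexicons = field(default_factory=Lexicons.default)
    kb: ReactionKB = field(default_factory=ReactionKB.default)
    group_window: int = 3  # tokens around a mention scanned for functional groups

    @classmethod
    def default(cls) -> "Resources":
        return cls()


def normalize_chemical(name: str) -> str:
    """Case/whitespace normalization used for KB and lexicon lookups."""
    return _normalize(name)
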