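"""Seeded synthetic PubTator corpora with planted reactions and distractors.

The generator emits abstracts built from templated sentences so that
every pipeline stage — parsing, candidate extraction, every labeling
function, the label model and the discriminative model — can be exercised
without downloads, including under the heavy class imbalance of real
corpora (positive-candidate rates configurable down to ~1.5%).

Gold relations are defined by template semantics at generation time (a
positive template plants exactly its substrate->product pair), never by
running the labeling functions, so evaluation against the gold set is not
circular.

Calibration: a positive sentence with n chemicals contributes n(n-1)
candidates and 1 gold pair, a distractor with k chemicals k(k-1) and 0.
Writing e_pos and e_neg for the expected candidates per positive and
distractor sentence under the template mix, the expected positive-
candidate rate at sentence-level reaction probability p is

    r = p / (p * e_pos + (1 - p) * e_neg)

which the generator inverts to hit a requested ``positive_candidate_rate``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .candidates import Candidate
from .corpus_io import read_pubtator
from .label_model import LabelMatrix
from .resources import ReactionKB, load_lexicon

GoldRelation = tuple[str, int, tuple[int, int], tuple[int, int]]
GoldRelationSet = set[GoldRelation]

# A tagged element sub-list for the element-distractor template.
_ELEMENT_MENTIONS = ("iron", "zinc", "copper", "manganese", "cobalt", "nickel")

_TITLES = (
    "Microbial transformation of small molecules.",
    "Metabolite interconversion in bacterial isolates.",
    "Biotransformation capacity of environmental strains.",
    "Enzymatic activities in anaerobic cultures.",
)


def _normalize_weights(dist: Mapping[int, float] | Mapping[str, float]) -> dict:
    total = float(sum(dist.values()))
    if total <= 0:
        raise ValueError("distribution weights must sum to a positive value")
    return {k: v / total for k, v in dist.items()}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; every probability is explicit.

    ``positive_candidate_rate`` is the target fraction of candidates that
    are gold positives; when set (the default emulates the ~5% imbalance
    of a reaction-enriched corpus) the sentence-level reaction rate is
    derived from it.  Set it to ``None`` to drive ``reaction_sentence_rate``
    directly.
    """

    n_docs: int = 200
    seed: int = 0
    sentences_per_doc: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.2, 3: 0.3, 4: 0.3, 5: 0.2})
    # chemical count of the generic list-distractor sentence (0 means a
    # chemical-free filler sentence); support spans 0-8
    chemicals_per_sentence: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.15, 2: 0.35, 3: 0.25, 4: 0.15,
                                 5: 0.05, 6: 0.03, 7: 0.01, 8: 0.01})
    positive_candidate_rate: float | None = 0.05
    reaction_sentence_rate: float = 0.25
    positive_templates: Mapping[str, float] = field(
        default_factory=lambda: {"converted": 0.3, "oxidized_by_enzyme": 0.15,
                                 "conversion_of": 0.2, "yields": 0.15,
                                 "reduced": 0.1, "converted_absence": 0.1})
    negative_templates: Mapping[str, float] = field(
        default_factory=lambda: {"list": 0.40, "or": 0.12, "treatment": 0.12,
                                 "ase": 0.12, "group": 0.12, "element": 0.12})
    kb_pair_rate: float = 0.3  # positive pairs drawn from the packaged KB
    vocabulary: Sequence[str] | None = None  # None -> packaged name list
    n_synthetic_names: int = 0  # extra CHEM_0001-style tokens appended

    def __post_init__(self) -> None:
        for rate in (self.kb_pair_rate, self.reaction_sentence_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.positive_candidate_rate is not None and \
                not (0.0 <= self.positive_candidate_rate <= 0.5):
            raise ValueError("positive_candidate_rate must be in [0, 0.5]")

    def resolve_vocabulary(self) -> list[str]:
        vocab = list(self.vocabulary) if self.vocabulary is not None \
            else sorted(load_lexicon("chemical_names"))
        vocab += [f"CHEM_{i:04d}" for i in range(1, self.n_synthetic_names + 1)]
        if not vocab:
            raise ValueError("chemical name vocabulary is empty")
        return vocab


# ---------------------------------------------------------------------------
# Sentence realizations: each returns (text, [(name, rel_start, rel_end)],
# gold pair index list [(i_substrate, i_product)])

_Real = tuple[str, list[tuple[str, int, int]], list[tuple[int, int]]]


def _compose(parts: Sequence[str], chem_flags: Sequence[bool]) -> tuple[str, list[tuple[int, int]]]:
    text = ""
    spans = []
    for part, is_chem in zip(parts, chem_flags):
        if is_chem:
            spans.append((len(text), len(text) + len(part)))
        text += part
    return text, spans


def _realize_positive(kind: str, rng: np.random.Generator, vocab: list[str],
                      kb_pairs: list[tuple[str, str]], kb_pair_rate: float) -> _Real:
    if kb_pairs and rng.random() < kb_pair_rate:
        sub, prod = kb_pairs[rng.integers(len(kb_pairs))]
    else:
        i, j = rng.choice(len(vocab), size=2, replace=False)
        sub, prod = vocab[i], vocab[j]
    if kind == "converted":
        parts = [sub.capitalize(), " is converted to ", prod, "."]
        flags = [True, False, True, False]
        names = [sub.capitalize(), prod]
        gold = [(0, 1)]
    elif kind == "oxidized_by_enzyme":
        parts = [sub.capitalize(), " was oxidized to ", prod,
                 " by a soluble dehydrogenase."]
        flags = [True, False, True, False]
        names = [sub.capitalize(), prod]
        gold = [(0, 1)]
    elif kind == "conversion_of":
        parts = ["Conversion of ", sub, " to ", prod, " was observed in cell extracts."]
        flags = [False, True, False, True, False]
        names = [sub, prod]
        gold = [(0, 1)]
    elif kind == "yields":
        parts = [sub.capitalize(), " yields ", prod, " under anaerobic conditions."]
        flags = [True, False, True, False]
        names = [sub.capitalize(), prod]
        gold = [(0, 1)]
    elif kind == "reduced":
        parts = [sub.capitalize(), " was reduced to ", prod, " in resting cells."]
        flags = [True, False, True, False]
        names = [sub.capitalize(), prod]
        gold = [(0, 1)]
    elif kind == "converted_absence":
        others = [v for v in vocab if v not in (sub, prod)]
        third = others[rng.integers(len(others))]
        parts = [sub.capitalize(), " is converted into ", prod,
                 " in the absence of ", third, "."]
        flags = [True, False, True, False, True, False]
        names = [sub.capitalize(), prod, third]
        gold = [(0, 1)]
    else:
        raise ValueError(f"unknown positive template {kind!r}")
    text, spans = _compose(parts, flags)
    return text, [(n, s, e) for n, (s, e) in zip(names, spans)], gold


def _pick(rng: np.random.Generator, vocab: list[str], k: int) -> list[str]:
    idx = rng.choice(len(vocab), size=k, replace=False)
    return [vocab[i] for i in idx]


def _realize_negative(kind: str, rng: np.random.Generator, vocab: list[str],
                      chem_count_dist: dict[int, float]) -> _Real:
    if kind == "list":
        ks = sorted(chem_count_dist)
        k = int(rng.choice(ks, p=[chem_count_dist[x] for x in ks]))
        if k == 0:
            fillers = ("The strain was isolated from soil samples.",
                       "Cultures were grown at thirty degrees overnight.",
                       "The pathway remains poorly characterized.")
            return fillers[rng.integers(len(fillers))], [], []
        if k == 1:
            k = 2
        chems = _pick(rng, vocab, k)
        parts: list[str] = []
        flags: list[bool] = []
        for i, chem in enumerate(chems):
            name = chem.capitalize() if i == 0 else chem
            if i > 0:
                parts.append(" and " if i == len(chems) - 1 else ", ")
                flags.append(False)
            parts.append(name)
            flags.append(True)
            chems[i] = name
        parts.append(" were measured in the culture supernatant.")
        flags.append(False)
        text, spans = _compose(parts, flags)
        return text, [(n, s, e) for n, (s, e) in zip(chems, spans)], []
    if kind == "or":
        a, b = _pick(rng, vocab, 2)
        parts = [a.capitalize(), " or ", b, " was added to the medium."]
        names = [a.capitalize(), b]
    elif kind == "treatment":
        a, b = _pick(rng, vocab, 2)
        parts = ["Patients were treated with ", a, " and ", b, "."]
        names = [a, b]
    elif kind == "ase":
        a, b = _pick(rng, vocab, 2)
        parts = [a.capitalize(), " dehydrogenase activity was detected in cultures containing ",
                 b, "."]
        names = [a.capitalize(), b]
    elif kind == "group":
        a, b = _pick(rng, vocab, 2)
        parts = ["The methyl ester of ", a, " was isolated together with ", b, "."]
        names = [a, b]
    elif kind == "element":
        elem = _ELEMENT_MENTIONS[rng.integers(len(_ELEMENT_MENTIONS))]
        a = _pick(rng, vocab, 1)[0]
        parts = [elem.capitalize(), " and ", a, " concentrations were determined."]
        names = [elem.capitalize(), a]
    else:
        raise ValueError(f"unknown negative template {kind!r}")
    flags = [p in names for p in parts]  # connector parts never equal a name
    text, spans = _compose(parts, flags)
    return text, [(n, s, e) for n, (s, e) in zip(names, spans)], []


def _expected_candidates(config: GeneratorConfig) -> tuple[float, float]:
    """Expected candidates per positive and per distractor sentence."""
    pos_w = _normalize_weights(config.positive_templates)
    e_pos = sum(w * (6.0 if kind == "converted_absence" else 2.0)
                for kind, w in pos_w.items())
    neg_w = _normalize_weights(config.negative_templates)
    chem_dist = _normalize_weights(config.chemicals_per_sentence)
    e_list = sum(w * max(k, 0) * (max(k, 0) - 1) for k, w in chem_dist.items())
    e_neg = sum(w * (e_list if kind == "list" else 2.0)
                for kind, w in neg_w.items())
    return e_pos, e_neg


def _reaction_rate(config: GeneratorConfig) -> float:
    if config.positive_candidate_rate is None:
        return config.reaction_sentence_rate
    r = config.positive_candidate_rate
    if r == 0.0:
        return 0.0
    e_pos, e_neg = _expected_candidates(config)
    p = r * e_neg / (1.0 - r * e_pos + r * e_neg)
    return min(max(p, 0.0), 1.0)


def generate_corpus(config: GeneratorConfig) -> tuple[str, GoldRelationSet]:
    """Generate PubTator text plus the planted gold relations.

    Deterministic given ``config.seed``; mention offsets are valid against
    ``title + " " + abstract``.  Gold relations are keyed by (doc_id,
    sentence_index, substrate span, product span) with spans global to the
    document text.
    """
    vocab = config.resolve_vocabulary()
    rng = np.random.default_rng(config.seed)
    kb_pairs = sorted(ReactionKB.default().pairs)
    p_reaction = _reaction_rate(config)
    pos_w = _normalize_weights(config.positive_templates)
    neg_w = _normalize_weights(config.negative_templates)
    chem_dist = _normalize_weights(config.chemicals_per_sentence)
    sent_dist = _normalize_weights(config.sentences_per_doc)
    sent_ks = sorted(sent_dist)
    pos_kinds = sorted(pos_w)
    neg_kinds = sorted(neg_w)

    out = io.StringIO()
    gold: GoldRelationSet = set()
    for d in range(config.n_docs):
        doc_id = str(90000000 + d)
        title = _TITLES[rng.integers(len(_TITLES))]
        n_sent = int(rng.choice(sent_ks, p=[sent_dist[k] for k in sent_ks]))
        abstract_parts: list[str] = []
        mention_rows: list[tuple[int, int, str]] = []
        offset = len(title) + 1  # abstract offsets in title + " " + abstract
        for s in range(n_sent):
            if rng.random() < p_reaction:
                kind = pos_kinds[rng.choice(len(pos_kinds),
                                            p=[pos_w[k] for k in pos_kinds])]
                text, chems, gold_pairs = _realize_positive(
                    kind, rng, vocab, kb_pairs, config.kb_pair_rate)
            else:
                kind = neg_kinds[rng.choice(len(neg_kinds),
                                            p=[neg_w[k] for k in neg_kinds])]
                text, chems, gold_pairs = _realize_negative(kind, rng, vocab, chem_dist)
            spans_abs = [(offset + s0, offset + e0) for _, s0, e0 in chems]
            for (name, _, _), (a, b) in zip(chems, spans_abs):
                mention_rows.append((a, b, name))
            for i_sub, i_prod in gold_pairs:
                # sentence index: title is sentence 0, abstract sentences follow
                gold.add((doc_id, s + 1, spans_abs[i_sub], spans_abs[i_prod]))
            abstract_parts.append(text)
            offset += len(text) + 1  # sentences joined by a single space
        abstract = " ".join(abstract_parts)
        out.write(f"{doc_id}|t|{title}\n")
        out.write(f"{doc_id}|a|{abstract}\n")
        for a, b, name in mention_rows:
            out.write(f"{doc_id}\t{a}\t{b}\t{name}\tChemical\t\n")
        out.write("\n")
    return out.getvalue(), gold


def gold_labels_for_candidates(gold: GoldRelationSet,
                               candidates: Iterable[Candidate]) -> dict[str, int]:
    """Per-candidate {+1, -1} labels from the planted relation set."""
    labels = {}
    for c in candidates:
        key = (c.doc_id, c.sentence_index, c.arg1.span, c.arg2.span)
        labels[c.candidate_id] = 1 if key in gold else -1
    return labels


def generate_label_matrix(n_candidates: int,
                          lf_accuracies: Sequence[float],
                          lf_propensities: Sequence[float],
                          prior: float,
                          seed: int = 0) -> tuple[LabelMatrix, np.ndarray]:
    """Simulate LF votes under the independent accuracy/propensity model.

    Oracle generator for label-model recovery tests: latent labels are
    drawn from the prior, each LF casts a vote with its propensity and
    matches the latent label with its accuracy.
    """
    alpha = np.asarray(lf_accuracies, dtype=float)
    rho = np.asarray(lf_propensities, dtype=float)
    if alpha.shape != rho.shape:
        raise ValueError("accuracies and propensities must align")
    rng = np.random.default_rng(seed)
    y = np.where(rng.random(n_candidates) < prior, 1, -1).astype(np.int8)
    cast = rng.random((n_candidates, len(alpha))) < rho
    correct = rng.random((n_candidates, len(alpha))) < alpha
    votes = np.where(correct, y[:, None], -y[:, None]).astype(np.int8)
    L = np.where(cast, votes, 0).astype(np.int8)
    names = [f"lf_sim_{j}" for j in range(len(alpha))]
    return LabelMatrix(data=L, lf_names=names), y


def adversarial_fixture() -> tuple[str, GoldRelationSet]:
    """The multi-product negation hard case, as a static one-document corpus.

    One sentence names two potential substrates (only one real) and three
    products; all substrate->product pairs look alike to co-occurrence
    rules, so a pair-enumerating predictor is wrong on half of them.  Gold
    marks exactly the true substrate's three pairs positive; substrates
    never pair with each other, nor products with products.
    """
    title = "Degradation of sulfur amino acids by bacterial lyases."
    sentence = ("Only D-cysteine but not L-cysteine was converted by D-CDes "
                "to pyruvate, H2S, and NH3.")
    doc_id = "77000001"
    chems = ["D-cysteine", "L-cysteine", "pyruvate", "H2S", "NH3"]
    offset = len(title) + 1
    spans = {}
    pos = 0
    for name in chems:
        start = sentence.index(name, pos)
        spans[name] = (offset + start, offset + start + len(name))
        pos = start + len(name)
    lines = [f"{doc_id}|t|{title}", f"{doc_id}|a|{sentence}"]
    for name in chems:
        a, b = spans[name]
        lines.append(f"{doc_id}\t{a}\t{b}\t{name}\tChemical\t")
    text = "\n".join(lines) + "\n\n"
    gold: GoldRelationSet = {
        (doc_id, 1, spans["D-cysteine"], spans[prod])
        for prod in ("pyruvate", "H2S", "NH3")
    }
    return text, gold


def materialize(pubtator_text: str, annotator=None):
    """Parse generated text into annotated documents + aligned mentions."""
    from .corpus_io import RuleAnnotator, align_mentions, annotate

    if annotator is None:
        annotator = RuleAnnotator()
    documents, mentions = read_pubtator(io.StringIO(pubtator_text))
    aligned = []
    for doc in documents:
        annotate(doc, annotator)
        aligned.extend(align_mentions(doc, [m for m in mentions
                                            if m.doc_id == doc.doc_id]))
    return documents, aligned
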