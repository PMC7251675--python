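"""Noise-aware discriminative classifier over sparse NLP features.

The discriminative model generalizes beyond the labeling functions: it is
a logistic regression over lexical/syntactic features of each candidate,
trained with sigmoid cross-entropy against *soft* targets — the training
marginals from the generative model — plus an elastic-net penalty.  Soft
targets are realized exactly by presenting each candidate twice, once as
positive with weight m_i and once as negative with weight 1 - m_i; the
weighted log-loss then equals the soft-target cross-entropy.  The
optimizer behind the module surface is scikit-learn's saga solver.

Feature templates (explicit, versioned; no hashing):

* lemma n-grams (n = 1..3) strictly between the mentions (textual order);
* lemma unigrams in a +/-3-token window flanking each mention
  (role-tagged: arg1_left, arg1_right, arg2_left, arg2_right);
* textual-order flag (product mention before substrate mention);
* token-distance bin between the mentions;
* POS-tag sequence between the mentions (truncated at 8 tags);
* indicator for an "-ase" token adjacent to either mention;
* one indicator per reaction keyword found between the mentions.

The vocabulary is built on the training split only, with a frequency
floor of 2 (a feature must occur in at least 2 training candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .candidates import Candidate
from .labeling_functions import LFContext, _keyword_between, _word_matches
from .resources import Resources

logger = logging.getLogger(__name__)

FEATURE_TEMPLATE_VERSION = "1"

FeatureVector = dict[str, float]

_DIST_BINS = (0, 1, 2, 5, 10)  # upper edges; last bin is open-ended
_POS_SEQ_MAX = 8
_WINDOW = 3


def _dist_bin(n_between: int) -> int:
    for b, edge in enumerate(_DIST_BINS):
        if n_between <= edge:
            return b
    return len(_DIST_BINS)


def extract_features(cand: Candidate, ctx: LFContext,
                     resources: Resources | None = None) -> FeatureVector:
    """Deterministic sparse features for one candidate in context."""
    res = resources if resources is not None else Resources.default()
    tokens = ctx.sentence.tokens
    between = [t.lemma for t in ctx.between_tokens]
    feats: FeatureVector = {}

    for n in (1, 2, 3):
        for i in range(len(between) - n + 1):
            feats[f"between_{n}gram={'_'.join(between[i:i + n])}"] = 1.0

    for role, rng in (("arg1", ctx.arg1_tokens), ("arg2", ctx.arg2_tokens)):
        for off in range(1, _WINDOW + 1):
            li = rng[0] - off
            if li >= 0:
                feats[f"{role}_left={tokens[li].lemma}"] = 1.0
            ri = rng[1] + off - 1
            if ri < len(tokens):
                feats[f"{role}_right={tokens[ri].lemma}"] = 1.0

    feats[f"order_reversed={int(cand.arg2.span[0] < cand.arg1.span[0])}"] = 1.0
    feats[f"dist_bin={_dist_bin(len(between))}"] = 1.0

    pos_seq = [t.pos for t in ctx.between_tokens[:_POS_SEQ_MAX]]
    feats[f"between_pos_seq={'_'.join(pos_seq)}"] = 1.0

    for rng in (ctx.arg1_tokens, ctx.arg2_tokens):
        nxt = rng[1]
        if nxt < len(tokens) and len(tokens[nxt].lemma) >= 5 and \
                tokens[nxt].lemma.endswith("ase"):
            feats["ase_adjacent"] = 1.0

    for entry in sorted(res.lexicons.reaction_keywords):
        if " " in entry:
            if _keyword_between(ctx, [entry]):
                feats[f"kw={entry}"] = 1.0
        elif any(_word_matches(lem, entry) for lem in between):
            feats[f"kw={entry}"] = 1.0
    return feats


# ---------------------------------------------------------------------------
# Vocabulary / vectorization


@dataclass
class FeatureVocabulary:
    """Explicit feature-name -> column index map, built on training data."""

    index: dict[str, int]

    @classmethod
    def build(cls, feature_dicts: Sequence[FeatureVector],
              min_count: int = 2) -> "FeatureVocabulary":
        counts: dict[str, int] = {}
        for fd in feature_dicts:
            for name in fd:
                counts[name] = counts.get(name, 0) + 1
        names = sorted(n for n, c in counts.items() if c >= min_count)
        return cls(index={n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.index)

    def transform(self, feature_dicts: Sequence[FeatureVector]) -> sp.csr_matrix:
        """Unknown features are ignored (logged at debug level)."""
        rows, cols, vals = [], [], []
        for i, fd in enumerate(feature_dicts):
            for name, val in fd.items():
                j = self.index.get(name)
                if j is None:
                    logger.debug("unknown feature %r ignored", name)
                    continue
                rows.append(i)
                cols.append(j)
                vals.append(val)
        return sp.csr_matrix((vals, (rows, cols)),
                             shape=(len(feature_dicts), len(self.index)))


# ---------------------------------------------------------------------------
# Resampling


@dataclass(frozen=True)
class ResamplePolicy:
    """Keep every confident positive, subsample the rest to ~10% of N.

    Negatives in this task are highly redundant, so most of them can be
    dropped without losing information; candidates whose marginal clears
    ``keep_threshold`` are always retained.
    """

    target_fraction: float = 0.10
    keep_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in (0, 1]")


def resample_training(candidate_ids: Sequence[str],
                      marginals: Mapping[str, float] | np.ndarray,
                      policy: ResamplePolicy) -> list[str]:
    """Seeded subsample of training candidates per the resampling policy."""
    if isinstance(marginals, np.ndarray):
        marg = {cid: float(m) for cid, m in zip(candidate_ids, marginals)}
    else:
        marg = dict(marginals)
    kept = [cid for cid in candidate_ids if marg[cid] >= policy.keep_threshold]
    rest = [cid for cid in candidate_ids if marg[cid] < policy.keep_threshold]
    target = round(policy.target_fraction * len(candidate_ids))
    if target < len(kept):
        logger.warning("target_fraction %.3f below kept fraction %.3f; "
                       "returning kept set", policy.target_fraction,
                       len(kept) / max(len(candidate_ids), 1))
        return kept
    n_extra = min(target - len(kept), len(rest))
    rng = np.random.default_rng(policy.seed)
    extra_idx = rng.choice(len(rest), size=n_extra, replace=False)
    extra = {rest[i] for i in extra_idx}
    # preserve original candidate order
    keep_set = set(kept) | extra
    return [cid for cid in candidate_ids if cid in keep_set]


# ---------------------------------------------------------------------------
# Training / prediction


@dataclass
class DiscriminativeParams:
    weights: dict[str, float]
    bias: float
    l1_ratio: float
    penalty_strength: float
    threshold: float = 0.5
    seed: int = 0
    template_version: str = FEATURE_TEMPLATE_VERSION
    vocabulary: FeatureVocabulary = field(default_factory=lambda: FeatureVocabulary({}))

    def save(self, stream: TextIO) -> None:
        stream.write(f"#rxnminer-model\tv{self.template_version}\n")
        stream.write(f"#bias\t{self.bias!r}\n")
        stream.write(f"#l1_ratio\t{self.l1_ratio!r}\n")
        stream.write(f"#penalty_strength\t{self.penalty_strength!r}\n")
        stream.write(f"#threshold\t{self.threshold!r}\n")
        stream.write(f"#seed\t{self.seed}\n")
        for name in sorted(self.weights):
            stream.write(f"{name}\t{self.weights[name]!r}\n")

    @classmethod
    def load(cls, stream: TextIO | Iterable[str]) -> "DiscriminativeParams":
        meta: dict[str, str] = {}
        weights: dict[str, float] = {}
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            key, val = line.split("\t", 1)
            if key.startswith("#"):
                meta[key[1:]] = val
            else:
                weights[key] = float(val)
        params = cls(
            weights=weights,
            bias=float(meta["bias"]),
            l1_ratio=float(meta["l1_ratio"]),
            penalty_strength=float(meta["penalty_strength"]),
            threshold=float(meta["threshold"]),
            seed=int(meta["seed"]),
            template_version=meta["rxnminer-model"].lstrip("v"),
        )
        params.vocabulary = FeatureVocabulary(
            {n: i for i, n in enumerate(sorted(weights))})
        return params


def soft_cross_entropy(scores: np.ndarray, targets: np.ndarray) -> float:
    """Mean sigmoid cross-entropy of probabilistic scores vs soft targets."""
    s = np.clip(scores, 1e-12, 1 - 1e-12)
    return float(-(targets * np.log(s) + (1 - targets) * np.log(1 - s)).mean())


def train_discriminative(feature_dicts: Sequence[FeatureVector],
                         marginals: np.ndarray,
                         l1_ratio: float = 0.5,
                         penalty_strength: float = 1e-3,
                         threshold: float = 0.5,
                         seed: int = 0,
                         tol: float = 1e-6,
                         max_iter: int = 20000,
                         min_feature_count: int = 2) -> DiscriminativeParams:
    """Fit the elastic-net logistic model on soft marginal targets.

    ``penalty_strength`` multiplies the elastic-net penalty on the *mean*
    loss (so duplicating every example leaves the optimum unchanged).
    """
    marginals = np.asarray(marginals, dtype=float)
    if len(feature_dicts) == 0:
        raise ValueError("no training examples")
    if np.allclose(marginals, marginals[0]):
        logger.warning("all marginals equal (%.3f); model will learn a constant",
                       marginals[0])
    vocab = FeatureVocabulary.build(feature_dicts, min_count=min_feature_count)
    X = vocab.transform(feature_dicts)

    # soft targets as two weighted hard examples per candidate
    X2 = sp.vstack([X, X], format="csr")
    y2 = np.concatenate([np.ones(X.shape[0]), np.zeros(X.shape[0])])
    w2 = np.concatenate([marginals, 1.0 - marginals])
    keep = w2 > 1e-12
    # sklearn's C scales the data term by C relative to a unit penalty on
    # the sum loss; C = 1 / (penalty_strength * total_weight) reproduces a
    # penalty on the per-example mean loss.
    C = 1.0 / (penalty_strength * float(w2[keep].sum()))
    clf = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=C,
        tol=tol, max_iter=max_iter, random_state=seed, fit_intercept=True,
    )
    clf.fit(X2[keep], y2[keep], sample_weight=w2[keep])
    names = sorted(vocab.index, key=vocab.index.get)
    weights = {n: float(w) for n, w in zip(names, clf.coef_[0]) if w != 0.0}
    params = DiscriminativeParams(
        weights=weights, bias=float(clf.intercept_[0]), l1_ratio=l1_ratio,
        penalty_strength=penalty_strength, threshold=threshold, seed=seed,
        vocabulary=vocab,
    )
    return params


def predict(params: DiscriminativeParams,
            feature_dicts: Sequence[FeatureVector]) -> np.ndarray:
    """Sigmoid scores in [0, 1]; every candidate is scored (coverage 1.0).

    Unknown features are ignored.
    """
    z = np.full(len(feature_dicts), params.bias)
    for i, fd in enumerate(feature_dicts):
        for name, val in fd.items():
            w = params.weights.get(name)
            if w is None:
                logger.debug("unknown feature %r ignored at predict time", name)
                continue
            z[i] += w * val
    return 1.0 / (1.0 + np.exp(-z))


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary labels from scores; a score exactly at threshold is positive."""
    return np.where(scores >= threshold, 1, -1).astype(np.int8)


def write_predictions(candidates: Sequence[Candidate], scores: np.ndarray,
                      stream: TextIO) -> None:
    """Prediction export: pmid, sentence number, both mentions with their
    character positions in the abstract text, and the model score."""
    stream.write("pmid\tsentence_index\targ1_text\targ1_start\targ1_end\t"
                 "arg2_text\targ2_start\targ2_end\tscore\n")
    for c, s in zip(candidates, scores):
        stream.write(
            f"{c.doc_id}\t{c.sentence_index}\t"
            f"{c.arg1.surface}\t{c.arg1.span[0]}\t{c.arg1.span[1]}\t"
            f"{c.arg2.surface}\t{c.arg2.span[0]}\t{c.arg2.span[1]}\t{s:.8f}\n"
        )
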