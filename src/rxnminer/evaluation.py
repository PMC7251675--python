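"""Corpus splitting, precision/recall/F metrics, and dev-set grid search.

Gold labels are per-candidate, i.e. per *ordered* mention pair: a correct
reaction extracted in reverse order scores as one false positive plus one
false negative.  Abstaining predictions count as predicted negative for
the confusion counts (an unrecovered positive is a miss), while model
coverage — the fraction of gold candidates receiving a definite
prediction — is reported alongside.

    P = TP / (TP + FP)        R = TP / (TP + FN)
    F_beta = (1 + beta^2) P R / (beta^2 P + R)

A metric whose denominator is zero is defined as 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

GoldLabels = Mapping[str, int]  # candidate_id -> {+1, -1}
Predictions = Mapping[str, int]  # candidate_id -> {+1, -1, 0 (abstain)}


@dataclass(frozen=True)
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    coverage: float
    precision: float
    recall: float
    f1: float
    f_beta: float
    beta: float

    def row(self, model: str) -> str:
        return (f"{model}\t{self.coverage:.2f}\t{self.precision:.2f}\t"
                f"{self.recall:.2f}\t{self.f1:.2f}")


def f_beta_score(precision: float, recall: float, beta: float = 1.0) -> float:
    """(1 + beta^2) P R / (beta^2 P + R), 0 when the denominator is 0."""
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def evaluate(predictions: Predictions, gold: GoldLabels,
             beta: float = 1.0) -> EvalReport:
    """Score predictions against per-candidate gold labels."""
    if not gold:
        raise ValueError("gold label set is empty")
    for cid in predictions:
        if cid not in gold:
            logger.warning("prediction for unknown candidate %r ignored", cid)
    tp = tn = fp = fn = 0
    definite = 0
    for cid, truth in gold.items():
        pred = predictions.get(cid, 0)
        if pred != 0:
            definite += 1
        effective = 1 if pred == 1 else -1  # abstain counts as negative
        if truth == 1 and effective == 1:
            tp += 1
        elif truth == 1:
            fn += 1
        elif effective == 1:
            fp += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        coverage=definite / len(gold),
        precision=precision, recall=recall,
        f1=f_beta_score(precision, recall, 1.0),
        f_beta=f_beta_score(precision, recall, beta),
        beta=beta,
    )


# ---------------------------------------------------------------------------
# Splits


@dataclass(frozen=True)
class SplitPlan:
    splits: dict[str, list[str]]
    seed: int

    def __getitem__(self, name: str) -> list[str]:
        return self.splits[name]


def split_corpus(doc_ids: Sequence[str], fractions: Mapping[str, float],
                 seed: int = 0) -> SplitPlan:
    """Document-level disjoint random partition, deterministic given seed.

    Split sizes follow largest-remainder rounding of ``fractions`` (which
    must sum to 1).  Raises if there are fewer documents than splits.
    """
    names = list(fractions)
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1 (got {total})")
    if len(doc_ids) < len(names):
        raise ValueError("fewer documents than splits")
    n = len(doc_ids)
    raw = {name: fractions[name] * n for name in names}
    sizes = {name: int(raw[name]) for name in names}
    remainder = n - sum(sizes.values())
    for name in sorted(names, key=lambda m: raw[m] - sizes[m], reverse=True):
        if remainder == 0:
            break
        sizes[name] += 1
        remainder -= 1
    rng = np.random.default_rng(seed)
    order = list(doc_ids)
    rng.shuffle(order)
    splits: dict[str, list[str]] = {}
    pos = 0
    for name in names:
        splits[name] = sorted(order[pos:pos + sizes[name]])
        pos += sizes[name]
    return SplitPlan(splits=splits, seed=seed)


# ---------------------------------------------------------------------------
# Gold-label TSV


def read_gold_tsv(stream: TextIO | Iterable[str]) -> dict[str, int]:
    """TSV candidate_id TAB label, label in {1, -1}."""
    gold = {}
    for k, line in enumerate(stream):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or \
                (k == 0 and line.startswith("candidate_id\t")):
            continue
        cid, label = line.split("\t")[:2]
        value = int(label)
        if value not in (1, -1):
            raise ValueError(f"gold label must be 1 or -1, got {label!r}")
        gold[cid] = value
    return gold


def write_gold_tsv(gold: Mapping[str, int], stream: TextIO) -> None:
    stream.write("candidate_id\tlabel\n")
    for cid in sorted(gold):
        stream.write(f"{cid}\t{gold[cid]}\n")


# ---------------------------------------------------------------------------
# Grid search


def grid_search(trainer: Callable[..., Predictions],
                grid: Mapping[str, Sequence],
                dev_gold: GoldLabels,
                beta: float = 1.0) -> tuple[dict, EvalReport]:
    """Exhaustive dev-set model selection over the Cartesian grid.

    ``trainer`` maps one hyperparameter cell (as keyword arguments) to
    dev-set predictions.  Selection maximizes dev F_beta; ties break by
    higher precision, then first cell in grid order.  A trainer failure
    skips that cell with a warning; if every cell fails, raises.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    names = list(grid)
    best: tuple[float, float, int] | None = None
    best_cell: dict | None = None
    best_report: EvalReport | None = None
    for k, values in enumerate(itertools.product(*(grid[n] for n in names))):
        cell = dict(zip(names, values))
        try:
            preds = trainer(**cell)
        except Exception:  # noqa: BLE001 - a bad cell must not kill the search
            logger.warning("grid cell %r failed; skipped", cell, exc_info=True)
            continue
        report = evaluate(preds, dev_gold, beta=beta)
        key = (report.f_beta, report.precision, -k)
        if best is None or key > best:
            best, best_cell, best_report = key, cell, report
    if best_cell is None or best_report is None:
        raise RuntimeError("all grid cells failed")
    return best_cell, best_report
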