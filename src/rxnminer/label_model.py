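"""Label-matrix diagnostics, majority vote, and the generative label model.

The label matrix L has one row per candidate and one column per labeling
function, with entries in {-1, 0, +1} (FALSE, ABSTAIN, TRUE).  Three
consumers are implemented:

* per-LF diagnostics (coverage / overlaps / conflicts) used to iterate on
  labeling-function design;
* majority vote — the sign of the row sum, abstaining on ties;
* a generative label model that treats the true label y_i in {+1, -1} as
  latent and models each LF j as voting independently given y with
  propensity rho_j (probability of not abstaining) and accuracy alpha_j
  (probability that a cast vote equals y).  It is fitted by EM without any
  gold labels, and its per-candidate posteriors P(y_i = +1 | L_i) are the
  *training marginals* consumed by the discriminative model.

The joint likelihood of a row under the model, given y, is

    P(L_i | y) = prod_j (1 - rho_j)^[L_ij=0] (rho_j alpha_j)^[L_ij=y]
                 (rho_j (1 - alpha_j))^[L_ij=-y]

with P(y=+1) = pi.  Because rho_j factors out of the posterior, the
marginals depend only on alpha_j and pi.  When a class prior is supplied
(the lever for heavy class imbalance) pi is held fixed in the M-step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

logger = logging.getLogger(__name__)

_EPS_CLAMP = 1e-4  # parameters kept in [1e-4, 1 - 1e-4]
ABSTAIN_TOL = 1e-9  # |marginal - prior| below this counts as "no signal"


@dataclass
class LabelMatrix:
    """Candidates x LFs matrix over {-1, 0, +1} with row/column names."""

    data: np.ndarray  # (N, J) int array
    lf_names: list[str]
    candidate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if self.data.shape[1] != len(self.lf_names):
            raise ValueError("lf_names length mismatch")
        if not np.isin(self.data, (-1, 0, 1)).all():
            raise ValueError("label matrix entries must be in {-1, 0, +1}")
        if not self.candidate_ids:
            self.candidate_ids = [str(i) for i in range(self.data.shape[0])]

    @property
    def n_candidates(self) -> int:
        return self.data.shape[0]

    @property
    def n_lfs(self) -> int:
        return self.data.shape[1]

    def to_triplets(self, stream: TextIO) -> None:
        """Sparse triplet TSV: candidate_id, lf_name, label (non-zero only)."""
        stream.write("candidate_id\tlf_name\tlabel\n")
        rows, cols = np.nonzero(self.data)
        for i, j in zip(rows, cols):
            stream.write(f"{self.candidate_ids[i]}\t{self.lf_names[j]}\t"
                         f"{int(self.data[i, j])}\n")

    @classmethod
    def from_triplets(cls, stream: TextIO | Iterable[str],
                      candidate_ids: Sequence[str],
                      lf_names: Sequence[str]) -> "LabelMatrix":
        row_of = {cid: i for i, cid in enumerate(candidate_ids)}
        col_of = {name: j for j, name in enumerate(lf_names)}
        data = np.zeros((len(candidate_ids), len(lf_names)), dtype=np.int8)
        for k, line in enumerate(stream):
            line = line.rstrip("\n")
            if not line or (k == 0 and line.startswith("candidate_id\t")):
                continue
            cid, name, label = line.split("\t")
            data[row_of[cid], col_of[name]] = int(label)
        return cls(data=data, lf_names=list(lf_names),
                   candidate_ids=list(candidate_ids))


@dataclass(frozen=True)
class LFStats:
    """Per-LF coverage / overlaps / conflicts proportions."""

    lf_names: list[str]
    coverage: np.ndarray
    overlaps: np.ndarray
    conflicts: np.ndarray

    def to_tsv(self, stream: TextIO) -> None:
        stream.write("lf_name\tcoverage\toverlaps\tconflicts\n")
        for j, name in enumerate(self.lf_names):
            stream.write(f"{name}\t{self.coverage[j]:.6f}\t{self.overlaps[j]:.6f}\t"
                         f"{self.conflicts[j]:.6f}\n")


def compute_lf_stats(L: LabelMatrix) -> LFStats:
    """Coverage, overlaps and conflicts per labeling function.

    coverage_j:  fraction of candidates the LF labels (non-abstain);
    overlaps_j:  fraction labeled by the LF *and* at least one other LF;
    conflicts_j: fraction labeled by the LF where some LF casts the
                 opposing label.  conflicts <= overlaps <= coverage.
    """
    if L.n_candidates == 0:
        raise ValueError("empty label matrix")
    M = L.data
    nonzero = M != 0
    row_nnz = nonzero.sum(axis=1)
    row_has_pos = (M == 1).any(axis=1)
    row_has_neg = (M == -1).any(axis=1)
    N = L.n_candidates
    coverage = nonzero.mean(axis=0)
    overlaps = (nonzero & (row_nnz > 1)[:, None]).mean(axis=0)
    conflict_entry = ((M == 1) & row_has_neg[:, None]) | ((M == -1) & row_has_pos[:, None])
    conflicts = conflict_entry.mean(axis=0)
    del N
    return LFStats(lf_names=list(L.lf_names), coverage=coverage,
                   overlaps=overlaps, conflicts=conflicts)


def majority_vote(L: LabelMatrix) -> tuple[np.ndarray, float]:
    """Sign-of-sum vote per candidate; ties (including all-abstain) abstain.

    Returns (predictions in {-1, 0, +1}, coverage = fraction non-abstain).
    """
    sums = L.data.sum(axis=1, dtype=np.int64)
    preds = np.sign(sums).astype(np.int8)
    coverage = float((preds != 0).mean()) if L.n_candidates else 0.0
    return preds, coverage


@dataclass
class GenerativeParams:
    """Fitted parameters of the independent accuracy/propensity model."""

    class_prior: float
    accuracies: np.ndarray  # alpha_j
    propensities: np.ndarray  # rho_j
    lf_names: list[str]
    log_likelihood_trace: list[float] = field(default_factory=list)
    converged: bool = True


def _row_log_factors(M: np.ndarray, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row log P(votes | y=+1), log P(votes | y=-1), rho factored out."""
    la, l1a = np.log(alpha), np.log1p(-alpha)
    pos_votes = M == 1
    neg_votes = M == -1
    log_pos = pos_votes @ la + neg_votes @ l1a
    log_neg = pos_votes @ l1a + neg_votes @ la
    return log_pos, log_neg


def _posterior(M: np.ndarray, alpha: np.ndarray, pi: float) -> np.ndarray:
    log_pos, log_neg = _row_log_factors(M, alpha)
    a = log_pos + np.log(pi)
    b = log_neg + np.log1p(-pi)
    m = np.maximum(a, b)
    return np.exp(a - m) / (np.exp(a - m) + np.exp(b - m))


def _log_likelihood(M: np.ndarray, alpha: np.ndarray, rho: np.ndarray,
                    pi: float) -> float:
    log_pos, log_neg = _row_log_factors(M, alpha)
    nonzero = M != 0
    lp_rho = (nonzero @ np.log(rho) + (~nonzero) @ np.log1p(-rho))
    a = log_pos + np.log(pi)
    b = log_neg + np.log1p(-pi)
    m = np.maximum(a, b)
    return float(np.sum(lp_rho + m + np.log(np.exp(a - m) + np.exp(b - m))))


def fit_generative(L: LabelMatrix,
                   prior: float | None = None,
                   seed: int = 0,
                   tol: float = 1e-6,
                   max_iter: int = 500,
                   min_accuracy: float = 0.5 + 1e-3) -> tuple[GenerativeParams, np.ndarray]:
    """Fit the generative label model by EM and return training marginals.

    If ``prior`` is given, the class prior pi is held fixed at that value
    (the class-imbalance lever); otherwise pi is re-estimated each M-step.
    Accuracies are initialized just above 0.5 with a small seeded jitter
    and floored at ``min_accuracy`` in the M-step.  The floor (default a
    hair above chance) encodes the unipolar-LF assumption that a cast
    vote never counts *against* its polarity: because every between-span
    rule fires identically on both orders of a mention pair, the
    unconstrained vote accuracy of a positive LF is at most 0.5, and
    unconstrained EM would flip such LFs into negative evidence.  Pass
    ``min_accuracy=1e-4`` for the unconstrained model.  Per-column the
    expected complete-data log-likelihood is concave in alpha_j, so
    clipping the M-step estimate to the box is the constrained maximizer
    and the observed log-likelihood remains non-decreasing; non-convergence
    within ``max_iter`` warns and returns the best estimate.
    """
    M = np.asarray(L.data, dtype=np.int8)
    if M.size == 0 or not (M != 0).any():
        raise ValueError("label matrix has no non-abstain entries")
    N, J = M.shape
    rng = np.random.default_rng(seed)

    rho = np.clip((M != 0).mean(axis=0), _EPS_CLAMP, 1 - _EPS_CLAMP)
    alpha = np.clip(0.7 + 0.05 * rng.standard_normal(J), 0.55, 0.95)
    pi = float(np.clip(prior if prior is not None else 0.5, _EPS_CLAMP, 1 - _EPS_CLAMP))

    trace: list[float] = []
    converged = False
    tau = _posterior(M, alpha, pi)
    for _ in range(max_iter):
        # M-step
        pos_votes = M == 1
        neg_votes = M == -1
        cast = pos_votes | neg_votes
        n_cast = cast.sum(axis=0)
        correct = pos_votes.T @ tau + neg_votes.T @ (1 - tau)
        with np.errstate(invalid="ignore"):
            alpha = np.where(n_cast > 0, correct / np.maximum(n_cast, 1), 0.5)
        alpha = np.clip(alpha, max(min_accuracy, _EPS_CLAMP), 1 - _EPS_CLAMP)
        if prior is None:
            pi = float(np.clip(tau.mean(), _EPS_CLAMP, 1 - _EPS_CLAMP))
        ll = _log_likelihood(M, alpha, rho, pi)
        if trace and ll < trace[-1] - 1e-9:
            logger.warning("EM log-likelihood decreased (%.3e); numerical noise",
                           trace[-1] - ll)
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # E-step
        tau = _posterior(M, alpha, pi)
    if not converged:
        logger.warning("generative model did not converge in %d iterations", max_iter)
    params = GenerativeParams(class_prior=pi, accuracies=alpha, propensities=rho,
                              lf_names=list(L.lf_names),
                              log_likelihood_trace=trace, converged=converged)
    marginals = _posterior(M, alpha, pi)
    return params, marginals


def score_candidates(params: GenerativeParams, L: LabelMatrix) -> np.ndarray:
    """Closed-form posterior P(y=+1 | row) per candidate; deterministic."""
    if L.n_lfs != len(params.accuracies):
        raise ValueError("label matrix / params dimension mismatch")
    return _posterior(np.asarray(L.data), params.accuracies, params.class_prior)


def marginals_coverage(marginals: np.ndarray, prior: float,
                       tol: float = ABSTAIN_TOL) -> float:
    """Fraction of candidates whose marginal moved off the prior.

    A row on which every LF abstained has posterior exactly equal to the
    prior; such candidates carry no LF signal and are the probabilistic
    analogue of a majority-vote abstention.
    """
    return float((np.abs(marginals - prior) >= tol).mean())


def marginal_predictions(marginals: np.ndarray, prior: float,
                         threshold: float = 0.5) -> np.ndarray:
    """Binary predictions from marginals with the no-signal rows abstaining."""
    preds = np.where(marginals >= threshold, 1, -1).astype(np.int8)
    preds[np.abs(marginals - prior) < ABSTAIN_TOL] = 0
    return preds


def write_marginals(candidate_ids: Sequence[str], marginals: np.ndarray,
                    stream: TextIO) -> None:
    stream.write("candidate_id\tmarginal\n")
    for cid, m in zip(candidate_ids, marginals):
        stream.write(f"{cid}\t{m:.8f}\n")


def read_marginals(stream: TextIO | Iterable[str]) -> dict[str, float]:
    out = {}
    for k, line in enumerate(stream):
        line = line.rstrip("\n")
        if not line or (k == 0 and line.startswith("candidate_id\t")):
            continue
        cid, m = line.split("\t")
        out[cid] = float(m)
    return out
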