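"""Detection power and precision/recall/F-measure over batches of results.

A dataset's causal pair counts as detected only if it appears, as an
exact unordered match, among the reported top-k pairs (no partial credit
for recovering one SNP of the pair).  Counts are aggregated over all
datasets before the ratios are formed (micro-averaging):

    power     = D_T / D
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-measure = 2 TP / (2 TP + FP + FN)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_io import TruthManifest
from .stage2 import DetectionResult

__all__ = [
    "EvaluationCounts",
    "score_batch",
    "detection_power",
    "precision",
    "recall",
    "f_measure",
]


@dataclass(frozen=True)
class EvaluationCounts:
    """Aggregated detection tallies over a batch of datasets."""

    D: int
    D_T: int
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if not 0 <= self.D_T <= self.D:
            raise ValueError("D_T must lie in [0, D]")
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.TP > self.D:
            raise ValueError("at most one true positive per dataset")


def score_batch(
    results: Sequence[DetectionResult],
    truths: Sequence[TruthManifest],
    top_k: int | None = None,
) -> EvaluationCounts:
    """Tally TP/FP/FN and detected-dataset counts over aligned result/truth lists.

    Per dataset the reported set is the top-k ranked pairs (``top_k=None``
    uses each result's own ``top_k``).  The causal pair in the reported set
    increments TP and D_T; a missing causal pair increments FN; every other
    reported pair increments FP.
    """
    if len(results) != len(truths):
        raise ValueError("results and truths must have equal length")
    d = d_t = tp = fp = fn = 0
    for result, truth in zip(results, truths):
        if result.dataset_id and truth.dataset_id and result.dataset_id != truth.dataset_id:
            raise ValueError(
                f"dataset_id mismatch: {result.dataset_id!r} vs {truth.dataset_id!r}"
            )
        k = top_k if top_k is not None else result.top_k
        reported = {s.pair for s in result.ranked_pairs[:k]}
        d += 1
        causal = tuple(sorted(truth.causal_pair))
        if causal in reported:
            d_t += 1
            tp += 1
            fp += len(reported) - 1
        else:
            fn += 1
            fp += len(reported)
    return EvaluationCounts(D=d, D_T=d_t, TP=tp, FP=fp, FN=fn)


def detection_power(counts: EvaluationCounts) -> float:
    """Fraction of datasets whose causal pair was recovered (D_T / D)."""
    if counts.D < 1:
        raise ValueError("detection power undefined for zero datasets")
    return counts.D_T / counts.D


def precision(counts: EvaluationCounts) -> float:
    """TP / (TP + FP); 0 when no pairs were reported at all."""
    denom = counts.TP + counts.FP
    return counts.TP / denom if denom else 0.0


def recall(counts: EvaluationCounts) -> float:
    """TP / (TP + FN); 0 when there was nothing to find."""
    denom = counts.TP + counts.FN
    return counts.TP / denom if denom else 0.0


def f_measure(counts: EvaluationCounts) -> float:
    """2 TP / (2 TP + FP + FN); 0 for an all-zero count."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    return 2 * counts.TP / denom if denom else 0.0
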