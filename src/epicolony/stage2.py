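"""Stage 2: exhaustive K2 re-scoring of the Stage-1 candidate SNP set.

Every unordered pair within the candidate set is scored with the
negative-log K2 score (lower = stronger association) and the results are
ranked ascending; the final report contains the top-k pairs.  CMPMI
values from the Stage-1 archive are carried through for reporting only —
the final ranking uses K2 alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

from .aco_stage1 import ACOConfig, CandidateArchive, run_stage1
from .bn_score import chi2_pvalue, k2_log_score, pair_contingency
from .data_io import GenotypeDataset

__all__ = ["PairScore", "DetectionResult", "exhaustive_k2", "detect"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairScore:
    """A scored SNP pair: identifiers, K2 log score, optional CMPMI and p-value."""

    pair: tuple[str, str]
    k2_log: float
    cmpmi: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("pair must name two distinct SNPs")
        if self.k2_log < 0:
            raise ValueError("k2_log must be nonnegative")
        object.__setattr__(self, "pair", tuple(sorted((str(a), str(b)))))


@dataclass(frozen=True)
class DetectionResult:
    """Final detector output: candidate SNPs and pairs ranked ascending by K2."""

    candidate_snps: frozenset[str]
    ranked_pairs: tuple[PairScore, ...]
    top_k: int
    dataset_id: str = ""

    @property
    def reported_pairs(self) -> tuple[PairScore, ...]:
        return self.ranked_pairs[: self.top_k]


def exhaustive_k2(
    dataset: GenotypeDataset,
    candidates: set[int] | list[int],
    archive: CandidateArchive | None = None,
) -> list[PairScore]:
    """Score every unordered pair within ``candidates`` by the K2 log score.

    Returns pairs sorted ascending by score (ties broken lexicographically
    by SNP ids); with fewer than 2 candidates an empty list is returned
    with a warning.
    """
    idx = sorted(set(candidates))
    if len(idx) < 2:
        warnings.warn("fewer than 2 candidate SNPs: nothing to score", stacklevel=2)
        return []
    archived = archive.entries if archive is not None else {}
    scores = []
    for a, b in combinations(idx, 2):
        table = pair_contingency(dataset, (a, b))
        scores.append(
            PairScore(
                pair=(dataset.snp_ids[a], dataset.snp_ids[b]),
                k2_log=k2_log_score(table),
                cmpmi=archived.get((a, b)),
            )
        )
    scores.sort(key=lambda s: (s.k2_log, s.pair))
    return scores


def detect(
    dataset: GenotypeDataset,
    config: ACOConfig,
    top_k: int = 1,
    max_candidates: int | None = None,
    compute_pvalues: bool = True,
    dataset_id: str = "",
) -> DetectionResult:
    """Run the full two-stage detector on one dataset.

    Stage 1 (ant colony guided by CMPMI) produces a candidate SNP set;
    Stage 2 exhaustively scores all pairs within it by the K2 score.
    ``max_candidates`` optionally truncates the candidate set, admitting
    SNPs from archived pairs in order of descending archive fitness.
    Chi-square p-values are attached to the reported top-k pairs only.
    Deterministic given ``config.seed``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    candidates, archive = run_stage1(dataset, config)
    if max_candidates is not None and len(candidates) > max_candidates:
        kept: set[int] = set()
        for pair, _fit in archive.best_pairs():
            for i in pair:
                if len(kept) < max_candidates:
                    kept.add(i)
        candidates = kept
    ranked = exhaustive_k2(dataset, candidates, archive)
    if compute_pvalues:
        id_to_idx = {s: i for i, s in enumerate(dataset.snp_ids)}
        reported = []
        for score in ranked[:top_k]:
            table = pair_contingency(
                dataset, (id_to_idx[score.pair[0]], id_to_idx[score.pair[1]])
            )
            reported.append(
                PairScore(
                    pair=score.pair,
                    k2_log=score.k2_log,
                    cmpmi=score.cmpmi,
                    p_value=chi2_pvalue(table),
                )
            )
        ranked = reported + ranked[top_k:]
    return DetectionResult(
        candidate_snps=frozenset(dataset.snp_ids[i] for i in candidates),
        ranked_pairs=tuple(ranked),
        top_k=min(top_k, len(ranked)) if ranked else top_k,
        dataset_id=dataset_id,
    )
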