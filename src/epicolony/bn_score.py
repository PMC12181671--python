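"""K2 Bayesian-network scoring of a SNP pair against the phenotype.

The K2 score evaluates the structure (SNP pair) -> phenotype under a
uniform Dirichlet prior (all hyperparameters 1).  For a binary phenotype
the marginal likelihood per genotype combination i with r_i samples split
as (r_i0, r_i1) is  r_i0! r_i1! / (r_i + 1)!, and the negative log of the
product over combinations is the score used here:

    score = sum_i [ ln (r_i + 1)!  -  ln r_i0!  -  ln r_i1! ]

computed with log-gamma so that cohorts of thousands of samples pose no
overflow problem.  Lower scores indicate stronger association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2_contingency

from .data_io import GenotypeDataset

__all__ = ["K2Table", "pair_contingency", "k2_log_score", "chi2_pvalue"]


@dataclass(frozen=True)
class K2Table:
    """Per-genotype-combination phenotype counts for a SNP pair.

    ``r_ij[i, j]`` counts samples whose pair genotype is combination ``i``
    and phenotype ``j``; rows with zero support are allowed and contribute
    nothing to the score.
    """

    r_ij: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_ij, dtype=np.int64)
        if r.ndim != 2 or r.shape[1] != 2:
            raise ValueError("K2Table requires an (I, 2) count matrix (binary phenotype)")
        if r.min() < 0:
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "r_ij", r)

    @property
    def r_i(self) -> np.ndarray:
        return self.r_ij.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.r_ij.sum())


def pair_contingency(dataset: GenotypeDataset, pair: tuple[int, int]) -> K2Table:
    """Tally the 9 ordered genotype combinations of a SNP pair by phenotype."""
    a, b = pair
    if a == b:
        raise ValueError("pair must consist of two distinct SNP indices")
    gx = dataset.genotypes[:, a].astype(np.int64)
    gz = dataset.genotypes[:, b].astype(np.int64)
    y = dataset.phenotype.astype(np.int64)
    flat = np.bincount((gx * 3 + gz) * 2 + y, minlength=18)
    return K2Table(flat.reshape(9, 2))


def k2_log_score(table: K2Table) -> float:
    """Negative-log K2 score of a contingency table (lower = stronger).

    Equals  sum_i [ sum_{b=1}^{r_i+1} ln b - sum_j sum_{d=1}^{r_ij} ln d ],
    evaluated via log-gamma.  Always >= 0; an empty table scores 0.
    """
    r_ij = table.r_ij
    contrib = gammaln(table.r_i + 2) - gammaln(r_ij + 1).sum(axis=1)
    # summing row contributions in sorted order makes the score exactly
    # invariant to row permutations
    return float(np.sort(contrib).sum())


def chi2_pvalue(table: K2Table) -> float:
    """Pearson chi-square p-value of phenotype association, occupied rows only.

    Degrees of freedom are (occupied rows - 1); with fewer than 2 occupied
    rows, or a degenerate phenotype margin, the association is undefined and
    1.0 is returned.
    """
    occ = table.r_ij[table.r_i > 0]
    if occ.shape[0] < 2:
        return 1.0
    if (occ.sum(axis=0) == 0).any():
        return 1.0
    res = chi2_contingency(occ, correction=False)
    return float(res.pvalue)
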