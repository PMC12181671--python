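"""Discrete information measures used as the Stage-1 search fitness.

All measures are maximum-likelihood plug-in estimates over the joint
distribution of two SNPs (X, Z) and the binary phenotype Y, in nats
(natural logarithm).  No pseudocounts are added; the convention
``0 * log(0/q) = 0`` applies throughout, which keeps the analytic
identities exact on exactly constructed probability tables.

The composite fitness CMPMI is a symmetrized variant of the multiscale
part mutual information (MPMI).  MPMI augments the conditional mutual
information CMI(X;Y|Z) — which over- or under-estimates direct
association when Z is strongly coupled to X or Y — with two extended
Kullback-Leibler correction terms and an exponential reweighting by the
marginal dependence of X and Y on the conditioning SNP Z:

    MPMI(X;Y|Z) = exp(2 MI(X;Z)) * exp(2 MI(Y;Z)) * CMI(X;Y|Z)
                  + D(p(x|z) || p*(x|z)) + D(p(y|z) || p*(y|z))

with p*(x|z) = sum_y p(x|z,y) p(y).  The exponential factors multiply
the CMI term only (standard operator precedence); this is the form under
which MPMI reduces to MI(X;Y) when (X, Y) are jointly independent of Z.
The alternative parenthesization, where the factors also scale the
divergence terms, is available as ``form="factored"`` for sensitivity
analysis.

CMPMI symmetrizes MPMI over the two SNPs of a pair:

    CMPMI(X, Z; Y) = [ MPMI(X;Y|Z) + MPMI(Z;Y|X) ] / 2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeDataset

__all__ = [
    "JointCounts3",
    "estimate_joint_counts",
    "mutual_information",
    "conditional_mutual_information",
    "extended_kl_divergence",
    "mpmi",
    "cmpmi",
    "cmpmi_from_counts",
]

MPMI_FORMS = ("additive", "factored")


@dataclass(frozen=True)
class JointCounts3:
    """Count (or probability) tensor over (genotype of X, genotype of Z, Y).

    ``counts[x, z, y]`` is the number of samples with those values; scaling
    by a positive constant is immaterial, so exact probability tables are
    accepted as well.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.float64)
        if c.ndim != 3:
            raise ValueError("JointCounts3 requires a 3-way tensor (x, z, y)")
        if c.min() < 0:
            raise ValueError("counts must be nonnegative")
        if c.sum() <= 0:
            raise ValueError("counts must sum to a positive total")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def swapped(self) -> "JointCounts3":
        """The same tensor with the roles of X and Z exchanged."""
        return JointCounts3(self.counts.transpose(1, 0, 2).copy())


def estimate_joint_counts(
    dataset: GenotypeDataset, snp_x: int, snp_z: int
) -> JointCounts3:
    """Tally the 3 x 3 x 2 joint counts of two SNP columns and the phenotype."""
    if snp_x == snp_z:
        raise ValueError("snp_x and snp_z must be distinct columns")
    gx = dataset.genotypes[:, snp_x].astype(np.int64)
    gz = dataset.genotypes[:, snp_z].astype(np.int64)
    y = dataset.phenotype.astype(np.int64)
    flat = np.bincount(gx * 6 + gz * 2 + y, minlength=18)
    return JointCounts3(flat.reshape(3, 3, 2))


def mutual_information(joint2) -> float:
    """Plug-in mutual information (nats) of a 2-way count table.

    Terms with a zero joint cell contribute 0; the result is clamped at 0
    (plug-in MI is analytically nonnegative, floating point can undershoot
    by ~1e-16).
    """
    c = np.asarray(joint2, dtype=np.float64)
    if c.ndim != 2:
        raise ValueError("mutual_information expects a 2-way table")
    total = c.sum()
    if total <= 0:
        raise ValueError("empty count table")
    p = c / total
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    prod = np.broadcast_to(pa * pb, p.shape)
    val = float(np.sum(p[mask] * (np.log(p[mask]) - np.log(prod[mask]))))
    return max(val, 0.0)


def conditional_mutual_information(jc: JointCounts3) -> float:
    """CMI(X;Y|Z) = sum p(x,y,z) log[ p(x,y,z) p(z) / (p(x,z) p(y,z)) ]."""
    p = jc.probs
    pz = p.sum(axis=(0, 2))          # (z,)
    pxz = p.sum(axis=2)              # (x, z)
    pzy = p.sum(axis=0)              # (z, y)
    num = p * pz[None, :, None]
    den = pxz[:, :, None] * pzy[None, :, :]
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(num[mask]) - np.log(den[mask]))))


def extended_kl_divergence(jc: JointCounts3, target: str = "x") -> float:
    """Extended Kullback-Leibler correction term of the part mutual information.

    For ``target="x"``:  D = sum_{x,y,z} p(x,y,z) log[ p(x|z) / p*(x|z) ]
    with p*(x|z) = sum_y p(x|z,y) p(y); ``target="y"`` swaps the roles of
    x and y.  Conditionals on unsupported events are taken as 0, which never
    zeroes the denominator on cells where p(x,y,z) > 0.
    """
    if target == "y":
        # swap the roles of the x and y axes: tensor (x, z, y) -> (y, z, x)
        return extended_kl_divergence(JointCounts3(jc.counts.transpose(2, 1, 0)), "x")
    if target != "x":
        raise ValueError("target must be 'x' or 'y'")
    p = jc.probs
    pz = p.sum(axis=(0, 2))          # (z,)
    pxz = p.sum(axis=2)              # (x, z)
    pzy = p.sum(axis=0)              # (z, y)
    py = p.sum(axis=(0, 1))          # (y,)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_x_given_z = np.where(pz[None, :] > 0, pxz / pz[None, :], 0.0)
        p_x_given_zy = np.where(pzy[None, :, :] > 0, p / pzy[None, :, :], 0.0)
    p_star = (p_x_given_zy * py[None, None, :]).sum(axis=2)  # (x, z)

    mask = p > 0
    num = np.broadcast_to(p_x_given_z[:, :, None], p.shape)
    den = np.broadcast_to(p_star[:, :, None], p.shape)
    # whenever p(x,y,z) > 0 the plug-in p*(x|z) has a strictly positive summand
    assert np.all(den[mask] > 0), "p*(x|z) vanished on a supported cell"
    return float(np.sum(p[mask] * (np.log(num[mask]) - np.log(den[mask]))))


def mpmi(jc: JointCounts3, form: str = "additive") -> float:
    """Multiscale part mutual information MPMI(X;Y|Z) of a joint count tensor.

    ``form="additive"`` (default) applies the exponential reweighting to the
    CMI term only; ``form="factored"`` scales the whole sum.
    """
    if form not in MPMI_FORMS:
        raise ValueError(f"form must be one of {MPMI_FORMS}")
    mi_xz = mutual_information(jc.counts.sum(axis=2))
    mi_yz = mutual_information(jc.counts.sum(axis=0))  # (z, y) margin; MI symmetric
    cmi = conditional_mutual_information(jc)
    d_x = extended_kl_divergence(jc, "x")
    d_y = extended_kl_divergence(jc, "y")
    scale = np.exp(2.0 * mi_xz) * np.exp(2.0 * mi_yz)
    if form == "additive":
        return float(scale * cmi + d_x + d_y)
    return float(scale * (cmi + d_x + d_y))


def cmpmi_from_counts(jc: JointCounts3, form: str = "additive") -> float:
    """CMPMI of a joint count tensor: mean of MPMI over both SNP orderings."""
    return 0.5 * (mpmi(jc, form) + mpmi(jc.swapped(), form))


def cmpmi(
    dataset: GenotypeDataset, pair: tuple[int, int], form: str = "additive"
) -> float:
    """CMPMI fitness of an unordered SNP pair in a case-control dataset.

    Symmetric by construction: the pair is canonically ordered before the
    tally, so ``cmpmi(D, (a, b))`` and ``cmpmi(D, (b, a))`` are bit-identical.
    """
    a, b = pair
    if a == b:
        raise ValueError("pair must consist of two distinct SNP indices")
    lo, hi = (a, b) if a < b else (b, a)
    jc = estimate_joint_counts(dataset, lo, hi)
    return cmpmi_from_counts(jc, form)
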