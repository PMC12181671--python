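"""Independent brute-force oracles for the information measures and K2 score.

Everything here is deliberately naive — explicit loops over tensor cells
and exact big-integer factorials — and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def _probs(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    return c / c.sum()


def mi_oracle(joint2) -> float:
    """MI by direct summation over the cells of a 2-way table."""
    p = _probs(joint2)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    total = 0.0
    for a in range(p.shape[0]):
        for b in range(p.shape[1]):
            if p[a, b] > 0:
                total += p[a, b] * math.log(p[a, b] / (pa[a] * pb[b]))
    return total


def cmi_oracle(counts3) -> float:
    """CMI(X;Y|Z) by direct summation; tensor indexed (x, z, y)."""
    p = _probs(counts3)
    pz = p.sum(axis=(0, 2))
    pxz = p.sum(axis=2)
    pzy = p.sum(axis=0)
    total = 0.0
    nx, nz, ny = p.shape
    for x in range(nx):
        for z in range(nz):
            for y in range(ny):
                if p[x, z, y] > 0:
                    total += p[x, z, y] * math.log(
                        p[x, z, y] * pz[z] / (pxz[x, z] * pzy[z, y])
                    )
    return total


def ekl_x_oracle(counts3) -> float:
    """D(p(x|z) || p*(x|z)) by direct summation; tensor indexed (x, z, y)."""
    p = _probs(counts3)
    pz = p.sum(axis=(0, 2))
    pxz = p.sum(axis=2)
    pzy = p.sum(axis=0)
    py = p.sum(axis=(0, 1))
    nx, nz, ny = p.shape
    total = 0.0
    for x in range(nx):
        for z in range(nz):
            for y in range(ny):
                if p[x, z, y] <= 0:
                    continue
                p_x_given_z = pxz[x, z] / pz[z]
                p_star = 0.0
                for y2 in range(ny):
                    if pzy[z, y2] > 0:
                        p_star += (p[x, z, y2] / pzy[z, y2]) * py[y2]
                total += p[x, z, y] * math.log(p_x_given_z / p_star)
    return total


def ekl_y_oracle(counts3) -> float:
    """D(p(y|z) || p*(y|z)): the x-oracle on the tensor with x and y swapped."""
    return ekl_x_oracle(np.asarray(counts3, dtype=float).transpose(2, 1, 0))


def mpmi_oracle(counts3, form: str = "additive") -> float:
    """MPMI composed from the brute-force sub-oracles."""
    c = np.asarray(counts3, dtype=float)
    scale = math.exp(2.0 * mi_oracle(c.sum(axis=2))) * math.exp(
        2.0 * mi_oracle(c.sum(axis=0))
    )
    cmi = cmi_oracle(c)
    dx = ekl_x_oracle(c)
    dy = ekl_y_oracle(c)
    if form == "additive":
        return scale * cmi + dx + dy
    return scale * (cmi + dx + dy)


def cmpmi_oracle(counts3, form: str = "additive") -> float:
    c = np.asarray(counts3, dtype=float)
    return 0.5 * (mpmi_oracle(c, form) + mpmi_oracle(c.transpose(1, 0, 2), form))


def k2_score_exact(r_ij) -> float:
    """-ln of the product-of-factorials K2 marginal likelihood (J = 2),
    with exact big-integer arithmetic."""
    r = np.asarray(r_ij, dtype=np.int64)
    num = 1
    den = 1
    for i in range(r.shape[0]):
        ri = int(r[i].sum())
        num *= math.factorial(r[i, 0]) * math.factorial(r[i, 1])
        den *= math.factorial(ri + 1)
    # -ln(num/den) = ln den - ln num, via exact integer logs
    return math.log(den) - math.log(num) if den < 10**300 else _log_ratio(den, num)


def _log_ratio(den: int, num: int) -> float:
    """ln(den/num) for huge exact integers."""
    import decimal

    decimal.getcontext().prec = 60
    return float(decimal.Decimal(den).ln() - decimal.Decimal(num).ln())


def k2_best_pair_exhaustive(dataset) -> tuple[str, str]:
    """Globally best pair by direct all-pairs K2 enumeration (naive loops)."""
    best = None
    best_key = None
    n = dataset.n_snps
    for a in range(n):
        for b in range(a + 1, n):
            ga = dataset.genotypes[:, a].astype(int)
            gb = dataset.genotypes[:, b].astype(int)
            y = dataset.phenotype.astype(int)
            r = np.zeros((9, 2), dtype=np.int64)
            for s in range(dataset.n_samples):
                r[ga[s] * 3 + gb[s], y[s]] += 1
            score = k2_score_exact(r)
            ids = tuple(sorted((dataset.snp_ids[a], dataset.snp_ids[b])))
            key = (score, ids)
            if best_key is None or key < best_key:
                best_key = key
                best = ids
    return best
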