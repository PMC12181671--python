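"""Case-control genotype simulator driven by two-locus penetrance models.

Each epistasis model is a pair of minor allele frequencies plus a 3 x 3
penetrance table P(case | genotype of SNP a, genotype of SNP b), with
rows/columns ordered (homozygous common, heterozygous, homozygous minor).
Eleven named benchmark models are built in: models 1-8 display marginal
effects, models 9-11 display none (and are therefore invisible to
single-SNP tests).

Generation uses simple rejection sampling: causal genotypes are drawn
from Hardy-Weinberg equilibrium at the model's allele frequencies, case
status is drawn from the penetrance cell, and draws accumulate until the
requested case and control quotas are both filled.  Background SNPs are
independent of phenotype and of each other, each at its own allele
frequency drawn uniformly from a configurable range.  The two causal
columns are placed at randomized positions recorded in the ground-truth
manifest.  No linkage disequilibrium, population structure or
missingness is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeDataset, TruthManifest

__all__ = [
    "EpistasisModel",
    "SimulationSpec",
    "model_registry",
    "hwe_genotype_probs",
    "simulate_dataset",
    "simulate_unascertained",
    "simulate_null",
    "simulate_batch",
]

_MIN_ACCEPTANCE = 1e-6


@dataclass(frozen=True)
class EpistasisModel:
    """A named two-locus disease model: MAFs plus a 3x3 penetrance table."""

    name: str
    maf_a: float
    maf_b: float
    penetrance: np.ndarray

    def __post_init__(self) -> None:
        for maf in (self.maf_a, self.maf_b):
            if not 0.0 < maf <= 0.5:
                raise ValueError("MAF must lie in (0, 0.5]")
        pen = np.asarray(self.penetrance, dtype=np.float64)
        if pen.shape != (3, 3):
            raise ValueError("penetrance must be a 3x3 matrix")
        if pen.min() < 0 or pen.max() > 1:
            raise ValueError("penetrance entries must lie in [0, 1]")
        if pen.max() <= 0:
            raise ValueError("at least one penetrance entry must be positive")
        pen.setflags(write=False)
        object.__setattr__(self, "penetrance", pen)

    def prevalence(self) -> float:
        """Population P(case) under HWE genotype frequencies."""
        pa = hwe_genotype_probs(self.maf_a)
        pb = hwe_genotype_probs(self.maf_b)
        return float(np.outer(pa, pb).ravel() @ self.penetrance.ravel())


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to generate one case-control dataset."""

    model: EpistasisModel
    n_cases: int = 2000
    n_controls: int = 2000
    n_snps: int = 100
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.n_snps < 2:
            raise ValueError("need at least 2 SNPs (the causal pair)")
        lo, hi = self.background_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("background MAF range must lie within (0, 0.5]")


# Benchmark penetrance tables, rows = genotype of SNP a (AA, Aa, aa),
# columns = genotype of SNP b (BB, Bb, bb).
_MODEL_TABLE: dict[str, tuple[float, float, list[list[float]]]] = {
    "Model1": (0.2, 0.2, [[0.087, 0.087, 0.087],
                          [0.087, 0.146, 0.190],
                          [0.087, 0.190, 0.247]]),
    "Model2": (0.5, 0.5, [[0.009, 0.009, 0.009],
                          [0.013, 0.006, 0.006],
                          [0.013, 0.006, 0.006]]),
    "Model3": (0.5, 0.5, [[0.092, 0.092, 0.092],
                          [0.092, 0.319, 0.319],
                          [0.092, 0.319, 0.319]]),
    "Model4": (0.2, 0.2, [[0.084, 0.084, 0.084],
                          [0.084, 0.210, 0.210],
                          [0.084, 0.210, 0.210]]),
    "Model5": (0.5, 0.5, [[0.052, 0.052, 0.052],
                          [0.052, 0.137, 0.137],
                          [0.052, 0.137, 0.137]]),
    "Model6": (0.5, 0.5, [[0.072, 0.164, 0.164],
                          [0.164, 0.072, 0.072],
                          [0.164, 0.072, 0.072]]),
    "Model7": (0.5, 0.5, [[0.067, 0.155, 0.155],
                          [0.155, 0.067, 0.067],
                          [0.155, 0.067, 0.067]]),
    "Model8": (0.3, 0.3, [[0.486, 0.960, 0.538],
                          [0.947, 0.004, 0.811],
                          [0.640, 0.606, 0.909]]),
    "Model9": (0.2, 0.5, [[0.103, 0.063, 0.124],
                          [0.098, 0.086, 0.069],
                          [0.021, 0.147, 0.059]]),
    "Model10": (0.5, 0.5, [[0.000, 0.000, 0.000],
                           [0.000, 0.050, 0.000],
                           [0.100, 0.000, 0.000]]),
    "Model11": (0.3, 0.3, [[0.000, 0.020, 0.000],
                           [0.020, 0.000, 0.020],
                           [0.000, 0.020, 0.000]]),
}


def model_registry() -> dict[str, EpistasisModel]:
    """The 11 built-in benchmark epistasis models, keyed by name."""
    return {
        name: EpistasisModel(name=name, maf_a=ma, maf_b=mb, penetrance=np.array(pen))
        for name, (ma, mb, pen) in _MODEL_TABLE.items()
    }


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def _draw_genotypes(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """Vectorized genotype draws from a (3,) probability triple."""
    cum = np.cumsum(probs)[:2]
    u = rng.random(size)
    return (u[:, None] > cum[None, :]).sum(axis=1).astype(np.int8)


def simulate_dataset(spec: SimulationSpec) -> tuple[GenotypeDataset, TruthManifest]:
    """Generate one case-control dataset with its ground-truth manifest.

    Rejection sampling fills the case and control quotas at the causal
    pair; excess draws of the already-complete class are discarded.  Rows
    are shuffled so phenotype carries no positional information.  Raises
    if the model cannot produce the requested classes (acceptance
    probability below 1e-6).
    """
    model = spec.model
    rng = np.random.default_rng(spec.seed)
    pa = hwe_genotype_probs(model.maf_a)
    pb = hwe_genotype_probs(model.maf_b)
    p_case = model.prevalence()
    p_control = 1.0 - p_case
    if spec.n_cases > 0 and p_case < _MIN_ACCEPTANCE:
        raise ValueError(f"{model.name}: case acceptance probability {p_case:.3g} too small")
    if spec.n_controls > 0 and p_control < _MIN_ACCEPTANCE:
        raise ValueError(f"{model.name}: control acceptance probability too small")

    n_total = spec.n_cases + spec.n_controls
    case_g: list[np.ndarray] = []
    ctrl_g: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    max_draws = int(50 * (spec.n_cases / p_case + spec.n_controls / p_control)) + 10_000
    drawn = 0
    batch = max(4096, n_total)
    while n_case_have < spec.n_cases or n_ctrl_have < spec.n_controls:
        if drawn > max_draws:
            raise RuntimeError(
                f"{model.name}: sampling budget exhausted before filling quotas"
            )
        ga = _draw_genotypes(rng, pa, batch)
        gb = _draw_genotypes(rng, pb, batch)
        is_case = rng.random(batch) < model.penetrance[ga, gb]
        drawn += batch
        if n_case_have < spec.n_cases:
            take = np.flatnonzero(is_case)[: spec.n_cases - n_case_have]
            case_g.append(np.column_stack((ga[take], gb[take])))
            n_case_have += take.size
        if n_ctrl_have < spec.n_controls:
            take = np.flatnonzero(~is_case)[: spec.n_controls - n_ctrl_have]
            ctrl_g.append(np.column_stack((ga[take], gb[take])))
            n_ctrl_have += take.size

    causal = np.vstack(case_g + ctrl_g)
    phenotype = np.concatenate(
        (np.ones(spec.n_cases, dtype=np.int8), np.zeros(spec.n_controls, dtype=np.int8))
    )

    # background SNPs: HWE, independent of phenotype, per-SNP MAF ~ U(range)
    n_bg = spec.n_snps - 2
    lo, hi = spec.background_maf_range
    bg_maf = rng.uniform(lo, hi, n_bg)
    bg_probs = np.column_stack(
        ((1 - bg_maf) ** 2, 2 * bg_maf * (1 - bg_maf), bg_maf**2)
    )
    cum = np.cumsum(bg_probs, axis=1)[:, :2]  # (n_bg, 2) thresholds
    u = rng.random((n_total, n_bg))
    background = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)

    # place the causal pair at randomized columns
    pos = rng.choice(spec.n_snps, size=2, replace=False)
    genotypes = np.empty((n_total, spec.n_snps), dtype=np.int8)
    bg_cols = [j for j in range(spec.n_snps) if j not in set(pos.tolist())]
    genotypes[:, bg_cols] = background
    genotypes[:, pos[0]] = causal[:, 0]
    genotypes[:, pos[1]] = causal[:, 1]

    perm = rng.permutation(n_total)
    genotypes = genotypes[perm]
    phenotype = phenotype[perm]

    width = len(str(spec.n_snps))
    snp_ids = tuple(f"SNP{j + 1:0{width}d}" for j in range(spec.n_snps))
    dataset_id = spec.dataset_id or f"{model.name}_seed{spec.seed}"
    dataset = GenotypeDataset(genotypes=genotypes, phenotype=phenotype, snp_ids=snp_ids)
    manifest = TruthManifest(
        dataset_id=dataset_id,
        causal_pair=(snp_ids[int(pos[0])], snp_ids[int(pos[1])]),
        model_name=model.name,
    )
    return dataset, manifest


def simulate_unascertained(
    model: EpistasisModel, n_samples: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw an unascertained cohort at the causal pair (no case/control quota).

    Returns (genotype_a, genotype_b, phenotype) arrays of length
    ``n_samples``; empirical P(case | g_a, g_b) converges to the model's
    penetrance table cell-wise.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    ga = _draw_genotypes(rng, hwe_genotype_probs(model.maf_a), n_samples)
    gb = _draw_genotypes(rng, hwe_genotype_probs(model.maf_b), n_samples)
    y = (rng.random(n_samples) < model.penetrance[ga, gb]).astype(np.int8)
    return ga, gb, y


def simulate_null(
    n_cases: int,
    n_controls: int,
    n_snps: int,
    seed: int = 0,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    dataset_id: str = "",
) -> GenotypeDataset:
    """A dataset with no causal pair: every SNP independent of phenotype."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    lo, hi = background_maf_range
    maf = rng.uniform(lo, hi, n_snps)
    cum = np.column_stack(((1 - maf) ** 2, 1 - maf**2))
    u = rng.random((n_total, n_snps))
    genotypes = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    phenotype = np.concatenate(
        (np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8))
    )
    perm = rng.permutation(n_total)
    width = len(str(n_snps))
    snp_ids = tuple(f"SNP{j + 1:0{width}d}" for j in range(n_snps))
    return GenotypeDataset(
        genotypes=genotypes[perm], phenotype=phenotype[perm], snp_ids=snp_ids
    )


def simulate_batch(
    model: EpistasisModel,
    n_datasets: int,
    n_cases: int = 2000,
    n_controls: int = 2000,
    n_snps: int = 100,
    base_seed: int = 0,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
) -> list[tuple[GenotypeDataset, TruthManifest]]:
    """Generate replicate datasets with sequentially derived seeds."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_datasets) % (2**31)
    out = []
    for r, s in enumerate(seeds):
        spec = SimulationSpec(
            model=model,
            n_cases=n_cases,
            n_controls=n_controls,
            n_snps=n_snps,
            background_maf_range=background_maf_range,
            seed=int(s),
            dataset_id=f"{model.name}_rep{r:03d}",
        )
        out.append(simulate_dataset(spec))
    return out
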