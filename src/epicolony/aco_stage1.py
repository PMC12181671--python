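"""Stage 1: improved ant-colony search over SNP pairs.

Each of ``m`` ants assembles an unordered SNP pair per iteration.  Every
pick either follows the classical pheromone-weighted rule (probability
proportional to tau_i^alpha * eta_i^beta over the not-yet-chosen SNPs) or,
to keep the colony out of cyclic paths, a uniformly random draw; which
branch fires is decided by comparing a uniform deviate q against the
threshold q0 (default: the reciprocal of the iteration count).  Pair
fitness is the CMPMI of the pair; pheromone deposited on each member SNP
equals that fitness, with evaporation at rate rho.

Two colony-level strategies shape the output:

* memory — per iteration the ants' solutions are sorted by descending
  fitness and a turning point (the rank with the largest discrete second
  difference of the fitness curve) separates candidate solutions, which
  are archived, from the rest;
* filter — the minimum fitness ever archived becomes a rising admission
  threshold for later iterations.

The union of SNPs over archived pairs is the candidate set handed to
Stage 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeDataset
from .measures import MPMI_FORMS, cmpmi, mutual_information

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "AntSolution",
    "CandidateArchive",
    "init_state",
    "select_combination",
    "update_pheromone",
    "turning_point",
    "run_stage1",
]

logger = logging.getLogger(__name__)

_TAU_FLOOR = 1e-12
_ETA_FLOOR = 1e-6


@dataclass(frozen=True)
class ACOConfig:
    """Colony parameters.

    ``q0=None`` resolves to 1/n_iterations at run time.  ``selection_semantics``
    chooses which branch of the randomized selection rule fires when the
    uniform deviate falls below q0: ``"literal"`` uses the pheromone rule,
    ``"swapped"`` the uniform draw.
    """

    n_ants: int = 200
    n_iterations: int = 70
    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.1
    q0: float | None = None
    tau0: float = 1.0
    eta_mode: str = "constant"
    selection_semantics: str = "literal"
    mpmi_form: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 3:
            raise ValueError("n_ants must be >= 3 (the turning point needs ranks 3..m)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.q0 is not None and not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if self.eta_mode not in ("constant", "marginal_mi"):
            raise ValueError("eta_mode must be 'constant' or 'marginal_mi'")
        if self.selection_semantics not in ("literal", "swapped"):
            raise ValueError("selection_semantics must be 'literal' or 'swapped'")
        if self.mpmi_form not in MPMI_FORMS:
            raise ValueError(f"mpmi_form must be one of {MPMI_FORMS}")

    @property
    def resolved_q0(self) -> float:
        return self.q0 if self.q0 is not None else 1.0 / self.n_iterations


@dataclass
class PheromoneState:
    """Per-SNP pheromone (tau) and heuristic information (eta), all > 0."""

    tau: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        if self.tau.shape != self.eta.shape or self.tau.ndim != 1:
            raise ValueError("tau and eta must be 1-D vectors of equal length")
        if (self.tau <= 0).any() or (self.eta <= 0).any():
            raise ValueError("tau and eta must be strictly positive")


@dataclass(frozen=True)
class AntSolution:
    """An unordered SNP pair with its CMPMI fitness."""

    pair: tuple[int, int]
    fitness: float

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("solution pair must contain distinct SNPs")
        if not np.isfinite(self.fitness):
            raise ValueError("fitness must be finite")
        object.__setattr__(self, "pair", (a, b) if a < b else (b, a))


@dataclass
class CandidateArchive:
    """Memory store of candidate solutions with a rising admission filter."""

    entries: dict[tuple[int, int], float] = field(default_factory=dict)
    filter_threshold: float = float("-inf")

    def update(self, iteration_solutions: list[AntSolution]) -> "CandidateArchive":
        """Archive solutions ranked before the turning point that beat the filter.

        Solutions are sorted by descending fitness; the turning point f
        (smallest rank with the largest second difference) cuts the sorted
        list, and solutions ranked strictly before f with fitness strictly
        above the current threshold are inserted (duplicates keep the best
        fitness).  The threshold then becomes the minimum fitness stored in
        the archive, which is non-decreasing over iterations.
        """
        if not iteration_solutions:
            return self
        ordered = sorted(iteration_solutions, key=lambda s: (-s.fitness, s.pair))
        fitnesses = [s.fitness for s in ordered]
        if len(ordered) < 3:
            candidates = ordered
        else:
            f = turning_point(fitnesses)
            candidates = ordered[: f - 1]
        for sol in candidates:
            if sol.fitness > self.filter_threshold:
                prev = self.entries.get(sol.pair)
                if prev is None or sol.fitness > prev:
                    self.entries[sol.pair] = sol.fitness
        if self.entries:
            self.filter_threshold = min(self.entries.values())
        return self

    def best_pairs(self) -> list[tuple[tuple[int, int], float]]:
        """Archived pairs sorted by descending fitness (ties by pair order)."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def snp_union(self) -> set[int]:
        return {i for pair in self.entries for i in pair}


def init_state(
    n_snps: int, config: ACOConfig, dataset: GenotypeDataset | None = None
) -> PheromoneState:
    """Initial pheromone state: tau = tau0 everywhere; eta per ``eta_mode``.

    ``marginal_mi`` sets eta_i to the mutual information of SNP i with the
    phenotype, floored at a small positive constant so selection
    probabilities stay well-defined on null SNPs.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    tau = np.full(n_snps, config.tau0, dtype=np.float64)
    if config.eta_mode == "constant":
        eta = np.ones(n_snps, dtype=np.float64)
    else:
        if dataset is None:
            raise ValueError("marginal_mi eta mode requires the dataset")
        eta = np.empty(n_snps, dtype=np.float64)
        y = dataset.phenotype.astype(np.int64)
        for i in range(n_snps):
            g = dataset.genotypes[:, i].astype(np.int64)
            joint = np.bincount(g * 2 + y, minlength=6).reshape(3, 2)
            eta[i] = max(mutual_information(joint), _ETA_FLOOR)
    return PheromoneState(tau=tau, eta=eta)


def select_combination(
    state: PheromoneState,
    config: ACOConfig,
    visited: set[int],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sequentially pick two distinct SNPs by the randomized selection rule.

    Per pick, a uniform deviate q decides the branch: q <= q0 applies the
    pheromone-weighted rule over the unvisited SNPs (probability
    proportional to tau^alpha * eta^beta), otherwise the pick is uniformly
    random over the unvisited SNPs.  ``selection_semantics="swapped"``
    inverts the branch.
    """
    n = state.tau.shape[0]
    available = np.array(
        [i for i in range(n) if i not in visited], dtype=np.int64
    ) if visited else np.arange(n, dtype=np.int64)
    if available.size < 2:
        raise ValueError("need at least 2 unvisited SNPs to form a pair")
    chosen: list[int] = []
    mask = np.ones(available.size, dtype=bool)
    for _ in range(2):
        pick = _pick_one(state, config, available[mask], rng)
        chosen.append(pick)
        mask &= available != pick
    a, b = chosen
    return (a, b) if a < b else (b, a)


def _pick_one(
    state: PheromoneState,
    config: ACOConfig,
    idx: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """One randomized pick from the SNP indices ``idx``."""
    q = rng.random()
    q0 = config.resolved_q0
    pheromone_branch = (q <= q0) if config.selection_semantics == "literal" else (q > q0)
    if pheromone_branch:
        w = state.tau[idx] ** config.alpha * state.eta[idx] ** config.beta
        total = w.sum()
        probs = w / total if total > 0 else np.full(idx.size, 1.0 / idx.size)
        return int(idx[rng.choice(idx.size, p=probs)])
    return int(idx[rng.integers(idx.size)])


def update_pheromone(
    state: PheromoneState, solutions: list[AntSolution], config: ACOConfig
) -> PheromoneState:
    """Evaporate and deposit: tau_i <- (1 - rho) tau_i + sum of fitnesses of
    solutions containing SNP i, floored at a tiny positive constant."""
    tau = (1.0 - config.rho) * state.tau
    for sol in solutions:
        for i in sol.pair:
            tau[i] += sol.fitness
    tau = np.maximum(tau, _TAU_FLOOR)
    return PheromoneState(tau=tau, eta=state.eta.copy())


def turning_point(fitnesses: list[float]) -> int:
    """Turning point of a descending fitness curve (1-based rank).

    Returns the rank g in {3..m} maximizing the discrete second difference
    (v[g] - v[g-1]) - (v[g-1] - v[g-2]); ties break to the smallest g.
    """
    v = np.asarray(fitnesses, dtype=np.float64)
    m = v.size
    if m < 3:
        raise ValueError("turning point needs at least 3 solutions")
    if (np.diff(v) > 1e-12).any():
        raise ValueError("fitnesses must be sorted in descending order")
    second_diff = v[2:] - 2.0 * v[1:-1] + v[:-2]
    return int(np.argmax(second_diff)) + 3


def run_stage1(
    dataset: GenotypeDataset,
    config: ACOConfig,
    log_progress: bool = False,
) -> tuple[set[int], CandidateArchive]:
    """Run the full Stage-1 colony and return (candidate SNP set, archive).

    Deterministic given ``config.seed``: all randomness flows from one
    seeded generator.  Pair fitnesses are cached, so repeated visits to a
    pair cost one dictionary lookup.
    """
    n = dataset.n_snps
    if n < 2:
        raise ValueError("dataset must contain at least 2 SNPs")
    rng = np.random.default_rng(config.seed)
    state = init_state(n, config, dataset)
    archive = CandidateArchive()
    fitness_cache: dict[tuple[int, int], float] = {}

    for t in range(config.n_iterations):
        solutions: list[AntSolution] = []
        for _ in range(config.n_ants):
            pair = select_combination(state, config, set(), rng)
            fit = fitness_cache.get(pair)
            if fit is None:
                fit = cmpmi(dataset, pair, form=config.mpmi_form)
                fitness_cache[pair] = fit
            solutions.append(AntSolution(pair=pair, fitness=fit))
        archive.update(solutions)
        state = update_pheromone(state, solutions, config)
        if log_progress:
            best = max(s.fitness for s in solutions)
            logger.info(
                "iteration %d: best fitness %.6g, archive size %d, threshold %.6g",
                t + 1, best, len(archive.entries), archive.filter_threshold,
            )
    return archive.snp_union(), archive
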