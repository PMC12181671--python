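# Methods

## Problem and model

`epicolony` detects two-order (pairwise) epistatic interactions in
case-control SNP data: genotypes are minor-allele counts x ∈ {0, 1, 2},
the phenotype Y is binary, and the target is the SNP pair whose *joint*
genotype distribution differs between cases and controls beyond what
either SNP explains alone. The pipeline has two stages — a stochastic
screen over pairs driven by an information-theoretic fitness, then an
exhaustive Bayesian re-scoring of the surviving SNP set — because an
all-pairs scan of n SNPs costs C(n, 2) contingency evaluations, which
the screen reduces to pairs within a much smaller candidate set.

## Information measures (Stage-1 fitness)

All measures are maximum-likelihood plug-in estimates over the
3 × 3 × 2 count tensor of (genotype of X, genotype of Z, Y), in nats.
No pseudocounts are used and 0·log(0/q) := 0; this choice keeps the
analytic identities below *exact* on exactly constructed probability
tables, which is what the property tests assert.

The multiscale part mutual information

    MPMI(X;Y|Z) = e^{2 MI(X;Z)} e^{2 MI(Y;Z)} · CMI(X;Y|Z) + D_X + D_Y

augments CMI(X;Y|Z) with extended Kullback–Leibler corrections
D_X = D(p(x|z) ‖ p\*(x|z)), p\*(x|z) = Σ_y p(x|z,y) p(y) (and
symmetrically D_Y), which counteract the over/under-estimation of
direct association that plain CMI suffers when the conditioning SNP is
strongly coupled to X or Y, and reweights the CMI term exponentially by
the marginal dependence of X and Y on Z. Two renderings of this
expression are conceivable; we use the one in which the exponential
factors multiply the CMI term only, because only under that reading
does MPMI reduce exactly to MI(X;Y) when (X, Y) ⟂ Z — an identity we
verify analytically in the tests. The alternative
(`form="factored"` / config `mpmi_form`) is kept for sensitivity
analysis.

MPMI treats the two SNPs of a pair asymmetrically, so the search
fitness is the symmetrized composite

    CMPMI(X, Z; Y) = [MPMI(X;Y|Z) + MPMI(Z;Y|X)] / 2,

computed after canonically ordering the pair so that the value is
bit-identical under argument exchange.

Conditionals on unsupported events are taken as 0 inside p\*; whenever
the weighting probability p(x,y,z) is positive, the plug-in denominator
has a strictly positive summand, so no division guard is ever needed
(an internal assertion enforces this).

## Ant-colony search (Stage 1)

Per iteration, each of m ants picks two distinct SNPs sequentially.
Each pick draws q ~ U(0,1): if q ≤ q₀ the classical pheromone rule
applies (P(i) ∝ τ_i^α η_i^β over the not-yet-picked SNPs), otherwise
the pick is uniformly random. q₀ defaults to 1/T (T = iterations),
which makes the search predominantly random with occasional
pheromone-guided exploitation; because this reading of the rule is
unusual, the inverted branch assignment is available as
`selection_semantics="swapped"` rather than silently resolved.
Pheromone update is τ_i ← (1 − ρ) τ_i + Σ_k CMPMI(S_k) over the ants k
whose pair contained SNP i, floored at 1e−12 to preserve positivity.

Heuristic information η is not part of the pair-selection problem's
definition; the default is η_i = 1 (pure pheromone guidance), with an
optional `marginal_mi` mode that sets η_i to the SNP's marginal MI with
the phenotype, floored at 1e−6.

Colony memory: each iteration's solutions are sorted by descending
fitness and cut at the turning point f = argmax_{g ∈ 3..m} of the
discrete second difference of the fitness curve (ties → smallest g);
solutions ranked before f enter the archive if their fitness strictly
exceeds the filter threshold, which is then reset to the minimum
archived fitness (non-decreasing over time). Archived pairs are
deduplicated keeping the best fitness. The candidate set passed to
Stage 2 is the union of SNPs over archived pairs.

Defaults: α = β = 1, ρ = 0.1, τ₀ = 1.0 (conventional ant-colony
settings; ρ and τ₀ are not dictated by the problem and are
configurable), m = 200 and T = 70 for 100-SNP datasets, m = 2000 and
T = 100 for 1000-SNP datasets (`--scale small|large`). All randomness
flows from a single seeded PCG64 generator; identical seeds give
bit-identical archives. Pair fitnesses are cached within a run.

## K2 scoring (Stage 2)

For a pair, samples are cross-tabulated over the nine ordered genotype
combinations i against the phenotype. Under a uniform Dirichlet prior
the marginal likelihood of the (pair → phenotype) structure is
∏_i r_i0! r_i1! / (r_i + 1)!, and the reported score is its negative
log, computed with log-gamma so n = 4000 poses no overflow; row
contributions are summed in sorted order, making the score exactly
invariant to row permutations. Lower scores rank higher; ties break
lexicographically on SNP ids, making the output a total order. The
final ranking uses K2 alone; CMPMI values are carried through for
reporting. An optional Pearson chi-square p-value (occupied rows × 2,
df = occupied − 1) accompanies reported pairs; it is a plain per-pair
association test with **no** correction for the selection of the top
pair out of many, and should be read accordingly.

## Simulator

Each benchmark model is a pair of MAFs and a 3 × 3 penetrance table
P(case | g_a, g_b); eleven are built in, spanning models with marginal
effects (1–8) and without (9–11). Generation draws causal genotypes
from Hardy–Weinberg equilibrium, assigns case status by the penetrance
cell, and accumulates by rejection until the case and control quotas
are filled (a bounded attempt budget guards against near-zero
acceptance). Defaults follow the benchmark layout: 4000 samples split
2000/2000 (the balanced split is the convention for such benchmarks and
is configurable), 100 SNPs, background MAFs ~ U(0.05, 0.5). Background
SNPs are mutually independent and independent of phenotype.

What the simulator does *not* emulate: linkage disequilibrium,
population stratification, genotyping error/missingness, covariates,
quantitative traits. Power measured on these datasets therefore speaks
to the detector's ability to find penetrance-driven pairs among
independent null SNPs, not to robustness against confounding or LD —
real-data performance can be lower.

## Evaluation

Detection means exact unordered match of the causal pair within the
reported top-k set (default k = 1); no partial credit for one correct
SNP. Counts are micro-averaged over datasets: power = D_T / D,
precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2TP/(2TP+FP+FN), with 0/0 conventions power undefined at D = 0 and
F = 0 for all-zero counts.

## Numerical and testing choices

* Measures are validated against naive cell-by-cell summation oracles
  (independent code, explicit loops) to 1e−10, and the K2 score against
  exact big-integer factorials to 1e−9.
* Analytic identities (MPMI = 0 under conditional independence;
  MPMI = MI(X;Y) under joint independence of Z) are asserted to 1e−12
  on exactly constructed tables, which the no-smoothing estimator makes
  possible.
* The benchmark-scale checks use 10 replicates per model (power on
  Models 3 and 5 at 100 SNPs × 4000 samples) and 20 null datasets at
  50 SNPs × 1000 samples with a proportionately scaled colony
  (m = 50, T = 30); these sizes give stable pass/fail behaviour while
  keeping the full suite to a few minutes.
* Simulator fidelity is asserted cell-wise at 99% *family-wise*
  binomial confidence (Bonferroni over the occupied penetrance cells of
  each model): a joint all-cells assertion at per-cell 99% would fail
  for roughly one seed in five by construction, which tests nothing
  about the simulator.
* Degenerate inputs: constant SNPs are legal (their contingency rows
  are simply unoccupied); datasets must contain both phenotype classes;
  identical indices in a pair are rejected everywhere.

## Known limitations

* The null-calibration property "top reported pair's raw chi-square
  p-value exceeds 0.05 on most null datasets" is *not* satisfied by a
  detector that exhaustively re-scores hundreds of pairs and reports
  the best: the winning pair is selected for extremeness, so its raw
  p-value concentrates near the minimum of ~10³ tests (measured
  0.0001–0.03 across 20 null runs). The corresponding test is kept as
  an honest failure; a selection-corrected p-value would be needed for
  calibrated null reporting, and none is defined for this pipeline.
* Only two-order interactions are searched; higher orders would need a
  different solution encoding and fitness.
* Stage 2 is quadratic in the candidate-set size; on null-like data
  the archive filter stays permissive and the candidate set can grow to
  most of the SNP panel (use `max_candidates` to cap it).
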