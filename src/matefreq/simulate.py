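"""Colony simulator and power-analysis grids.

Colonies are generated under the model itself: a diploid queen drawn from
Hardy-Weinberg proportions, haploid fathers drawn from population
frequencies, offspring inheriting one uniform maternal allele plus their
father's allele, observation noise from the dropout/mistyping error model,
and optional missingness and planted drifters (offspring of a second,
unrelated simulated queen).

The power grids mirror the validation design for this class of method:
colonies of 20 offspring with strong paternity skew (every father beyond the
first sires exactly one offspring — the hardest case for separating extra
fathers from genotyping error), replicated over a grid of true father counts
(1-6) and error rates (0.01, 0.05, 0.1), and over locus counts (2, 4, 8, 16
loci of 3 equally frequent alleles at error rate 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import QUEEN, WORKER, AlleleFrequencies, GenotypeTable
from .sampler import SamplerConfig, run_sampler
from .summaries import summarize

#: father-count reporting ceiling for power matrices
K_MAX = 8

#: default synthetic frequency model standing in for the wild reference
#: population: 11 loci x 5 equally frequent alleles
DEFAULT_N_LOCI = 11
DEFAULT_N_ALLELES = 5


@dataclass
class SimulationSpec:
    """Ground-truth recipe for one simulated colony."""

    n_loci: int = DEFAULT_N_LOCI
    alleles_per_locus: int = DEFAULT_N_ALLELES
    freqs: AlleleFrequencies | None = None   # overrides the two fields above
    n_offspring: int = 20
    n_fathers: int = 1
    skew_rule: str = "skewed"            # or "custom"
    proportions: tuple = ()                  # used when skew_rule == "custom"
    e1: float = 0.0
    e2: float = 0.0
    missing_rate: float = 0.0
    queen_observed: bool = True
    n_drifters: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_fathers < 1 or self.n_fathers > self.n_offspring:
            raise ValueError("need 1 <= n_fathers <= n_offspring")
        if self.skew_rule not in ("skewed", "custom"):
            raise ValueError(f"unknown skew_rule {self.skew_rule!r}")
        if self.skew_rule == "custom" and len(self.proportions) != self.n_fathers:
            raise ValueError("custom skew needs one proportion per father")
        if not (0.0 <= self.e1 <= 0.5 and 0.0 <= self.e2 <= 0.5):
            raise ValueError("error rates must lie in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_drifters < 0:
            raise ValueError("n_drifters must be >= 0")

    def frequency_model(self) -> AlleleFrequencies:
        if self.freqs is not None:
            return self.freqs
        names = [f"L{l + 1}" for l in range(self.n_loci)]
        return AlleleFrequencies.uniform(names, self.alleles_per_locus)

    def father_counts(self) -> np.ndarray:
        """Offspring per father. Under the skewed rule one father sires the
        majority and each additional father exactly one offspring."""
        if self.skew_rule == "skewed":
            counts = np.ones(self.n_fathers, dtype=int)
            counts[0] = self.n_offspring - (self.n_fathers - 1)
            return counts
        props = np.asarray(self.proportions, dtype=float)
        props = props / props.sum()
        counts = np.floor(props * self.n_offspring).astype(int)
        # distribute the remainder by largest fractional part
        rem = self.n_offspring - counts.sum()
        order = np.argsort(-(props * self.n_offspring - counts))
        for i in range(rem):
            counts[order[i % len(counts)]] += 1
        return counts


def _draw_diploid(rng, p):
    return (rng.choice(len(p), p=p), rng.choice(len(p), p=p))


def _observe_genotype(rng, geno, e1, e2, k):
    """Push a true diploid genotype through the generative error process."""
    a, b = geno
    if a != b and rng.random() < e1:
        keep = a if rng.random() < 0.5 else b
        a = b = keep
    out = []
    for allele in (a, b):
        if rng.random() < e2:
            others = [x for x in range(k) if x != allele]
            allele = others[rng.integers(len(others))]
        out.append(allele)
    return tuple(out)


def simulate_colony(spec: SimulationSpec):
    """Generate one colony and its ground truth.

    Returns ``(GenotypeTable, truth)`` where truth records the queen's and
    fathers' latent genotypes, per-offspring father assignments, drifter
    flags, and the error rates used.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequency_model()
    loci = list(freqs.loci)
    L = len(loci)
    kvec = [freqs.n_alleles(name) for name in loci]
    pvec = [freqs.p(name) for name in loci]
    labels = [freqs.labels(name) for name in loci]

    queen = [_draw_diploid(rng, pvec[l]) for l in range(L)]
    fathers = [[rng.choice(kvec[l], p=pvec[l]) for l in range(L)]
               for _ in range(spec.n_fathers)]
    counts = spec.father_counts()
    assignment = np.repeat(np.arange(spec.n_fathers), counts)

    true_offspring = []
    for f in assignment:
        geno = []
        for l in range(L):
            m = queen[l][rng.integers(2)]
            geno.append((m, fathers[f][l]))
        true_offspring.append(geno)

    drifter_queen = [_draw_diploid(rng, pvec[l]) for l in range(L)]
    drifter_truth = []
    for _ in range(spec.n_drifters):
        sire = [rng.choice(kvec[l], p=pvec[l]) for l in range(L)]
        geno = []
        for l in range(L):
            m = drifter_queen[l][rng.integers(2)]
            geno.append((m, sire[l]))
        drifter_truth.append(geno)

    ids, roles, entries = [], [], []
    if spec.queen_observed:
        ids.append("queen")
        roles.append(QUEEN)
        entries.append([
            _observe_genotype(rng, queen[l], spec.e1, spec.e2, kvec[l])
            for l in range(L)])
    for i, geno in enumerate(true_offspring + drifter_truth):
        ids.append(f"w{i + 1}")
        roles.append(WORKER)
        entries.append([
            _observe_genotype(rng, geno[l], spec.e1, spec.e2, kvec[l])
            for l in range(L)])
    if spec.missing_rate > 0:
        for row in entries:
            for l in range(L):
                if rng.random() < spec.missing_rate:
                    row[l] = None

    def decode(geno_row):
        return [tuple(sorted((labels[l][geno_row[l][0]], labels[l][geno_row[l][1]])))
                for l in range(L)]

    named = [[None if e is None else (labels[l][e[0]], labels[l][e[1]])
              for l, e in enumerate(row)] for row in entries]
    table = GenotypeTable(ids, loci, named, roles)
    n_real = len(true_offspring)
    truth = {
        "queen_genotype": decode([queen[l] for l in range(L)]),
        "father_alleles": [[labels[l][f[l]] for l in range(L)] for f in fathers],
        "father_of": {f"w{i + 1}": int(assignment[i]) for i in range(n_real)},
        "is_drifter": {f"w{i + 1}": i >= n_real
                       for i in range(n_real + spec.n_drifters)},
        "father_counts": counts.tolist(),
        "e1": spec.e1,
        "e2": spec.e2,
        "seed": spec.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# power grids


@dataclass
class PowerResult:
    """Tidy per-replicate records plus per-cell accuracy matrices.

    ``accuracy[cell]`` is a (K_MAX, n_true_K) column-stochastic matrix:
    entry (r, c) is the average posterior probability of ``r + 1`` fathers
    given the cell's c-th true father count.
    """

    records: pd.DataFrame
    accuracy: dict
    true_k_values: tuple
    config: dict = field(default_factory=dict)

    def accuracy_matrix(self, cell) -> np.ndarray:
        return self.accuracy[cell]

    def diagonal_accuracy(self, cell) -> np.ndarray:
        """Average posterior probability on the true K, per true K."""
        m = self.accuracy[cell]
        return np.array([m[k - 1, c] for c, k in enumerate(self.true_k_values)])

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


#: sampler schedule used inside simulation studies (lighter than the
#: single-colony default; still 1,000 retained samples)
POWER_SAMPLER = dict(sweeps=3000, burn_in=1000, thin=2, drifter_prior=0.0)


def _replicate_seeds(root_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(root_seed)
    return (ss.generate_state(n, dtype=np.uint32) % (2 ** 31 - 1)).astype(np.int64)


def _posterior_vector(summary) -> np.ndarray:
    """p_fathers over 1..K_MAX with any overflow mass folded into K_MAX."""
    v = np.zeros(K_MAX)
    for k, pr in summary.p_fathers.items():
        v[min(int(k), K_MAX) - 1] += pr
    return v


def _run_cell(cell, base_spec: SimulationSpec, true_k_values, n_reps,
              sampler_kwargs, seeds, seed_offset, records):
    """Simulate and fit n_reps colonies per true K for one grid cell."""
    acc = np.zeros((K_MAX, len(true_k_values)))
    for c, k_true in enumerate(true_k_values):
        vecs = np.zeros((n_reps, K_MAX))
        for rep in range(n_reps):
            seed = int(seeds[seed_offset])
            seed_offset += 1
            spec = replace(base_spec, n_fathers=k_true, seed=seed)
            table, _ = simulate_colony(spec)
            cfg = SamplerConfig(seed=seed, **sampler_kwargs)
            samples = run_sampler(table, spec.frequency_model(), cfg,
                                  min_polymorphic_loci=0)
            summ = summarize(samples)
            vecs[rep] = _posterior_vector(summ)
            records.append({
                "cell": cell, "true_K": k_true, "replicate": rep,
                "seed": seed, "map_K": summ.map_k,
                "e1_hat": summ.e1_mean, "e2_hat": summ.e2_mean,
                **{f"p{k + 1}": vecs[rep, k] for k in range(K_MAX)}})
        acc[:, c] = vecs.mean(axis=0)
    return acc, seed_offset


def run_power_grid(true_k_values=(1, 2, 3, 4, 5, 6),
                   error_rates=(0.01, 0.05, 0.1),
                   n_reps: int = 100,
                   base_spec: SimulationSpec | None = None,
                   sampler_config: dict | None = None,
                   seed: int = 0) -> PowerResult:
    """Father-count x error-rate accuracy grid.

    For each (error rate, true K) cell, simulate ``n_reps`` skewed colonies,
    run the sampler with both rates free, and average the posterior vector
    over the number of fathers. Cells are keyed by error rate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_spec = base_spec or SimulationSpec()
    sampler_kwargs = dict(POWER_SAMPLER)
    if sampler_config:
        sampler_kwargs.update(sampler_config)
    true_k_values = tuple(true_k_values)
    seeds = _replicate_seeds(seed, len(error_rates) * len(true_k_values) * n_reps)
    records: list = []
    accuracy = {}
    off = 0
    for rate in error_rates:
        spec = replace(base_spec, e1=rate, e2=rate)
        accuracy[rate], off = _run_cell(rate, spec, true_k_values, n_reps,
                                        sampler_kwargs, seeds, off, records)
    return PowerResult(pd.DataFrame(records), accuracy, true_k_values,
                       config={"grid": "fathers", "n_reps": n_reps,
                               "error_rates": list(error_rates),
                               "seed": seed, **sampler_kwargs})


def run_loci_grid(loci_counts=(2, 4, 8, 16),
                  true_k_values=(1, 2, 3, 4, 5, 6),
                  n_reps: int = 100,
                  error_rate: float = 0.05,
                  n_alleles: int = 3,
                  sampler_config: dict | None = None,
                  seed: int = 0) -> PowerResult:
    """Locus-count accuracy grid: 3 equally frequent alleles per locus and a
    fixed error rate of 0.05 for both classes, by default. Cells are keyed
    by locus count."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sampler_kwargs = dict(POWER_SAMPLER)
    if sampler_config:
        sampler_kwargs.update(sampler_config)
    true_k_values = tuple(true_k_values)
    seeds = _replicate_seeds(seed, len(loci_counts) * len(true_k_values) * n_reps)
    records: list = []
    accuracy = {}
    off = 0
    for n_loci in loci_counts:
        spec = SimulationSpec(n_loci=n_loci, alleles_per_locus=n_alleles,
                              e1=error_rate, e2=error_rate)
        accuracy[n_loci], off = _run_cell(n_loci, spec, true_k_values, n_reps,
                                          sampler_kwargs, seeds, off, records)
    return PowerResult(pd.DataFrame(records), accuracy, true_k_values,
                       config={"grid": "loci", "n_reps": n_reps,
                               "loci_counts": list(loci_counts),
                               "error_rate": error_rate,
                               "n_alleles": n_alleles,
                               "seed": seed, **sampler_kwargs})
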