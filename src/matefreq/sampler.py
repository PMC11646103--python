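"""Gibbs sampler targeting the joint posterior of paternity partition,
drifter indicators, error rates, and latent maternal genotypes.

Defaults retain 1,000 posterior samples (12,000 sweeps, 2,000 burn-in,
thinning 10). The chain is initialized from the monandrous state (all
offspring one full-sib group under the queen), error rates at 0.05, and
maternal genotypes drawn from their full conditionals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .error_model import pair_index
from .genotypes import AlleleFrequencies, GenotypeTable, estimate_allele_frequencies


class ColonyNotEvaluableError(ValueError):
    """Raised when a colony fails the polymorphic-locus minimum."""

    def __init__(self, message, n_polymorphic, minimum):
        super().__init__(message)
        self.n_polymorphic = n_polymorphic
        self.minimum = minimum


@dataclass
class SamplerConfig:
    """Tunable knobs of the Gibbs sampler.

    alpha : Dirichlet-process concentration over full-sib groups.
    drifter_prior : prior probability that an offspring belongs to the
        latent second (unobserved) queen; 0 disables drifter modeling.
    sweeps, burn_in, thin : chain schedule; retained samples =
        floor((sweeps - burn_in) / thin).
    queen_observed_with_error : treat the queen's observed genotype as
        error-prone data on her latent true genotype (she is genotyped by
        the same assay as her workers). When False an observed queen
        genotype is taken as exact.
    e1_init, e2_init : starting error rates; also the fixed rates when
        ``fix_rates`` is True.
    step : initial Metropolis step on the logit scale, adapted during
        burn-in toward 20-50% acceptance.
    """

    alpha: float = 1.0
    drifter_prior: float = 0.05
    sweeps: int = 12000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 0
    queen_observed_with_error: bool = True
    e1_init: float = 0.05
    e2_init: float = 0.05
    fix_rates: bool = False
    step: float = 0.3

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.drifter_prior < 0.5):
            raise ValueError("drifter_prior must lie in [0, 0.5)")
        if not (self.sweeps > self.burn_in >= 0):
            raise ValueError("need sweeps > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= int(self.seed) < 2 ** 31):
            raise ValueError("seed must lie in [0, 2^31)")

    @property
    def n_retained(self) -> int:
        return (self.sweeps - self.burn_in) // self.thin


@dataclass
class EncodedColony:
    """Integer encoding of one colony against a frequency table."""

    obs: np.ndarray          # (n_workers, L) genotype index, -1 missing
    qobs: np.ndarray         # (L,) queen genotype index, -1 unobserved
    kvec: np.ndarray         # (L,) alleles per locus
    nG: np.ndarray           # (L,) genotypes per locus
    ga: np.ndarray           # (L, Gmax) first allele of genotype index
    gb: np.ndarray           # (L, Gmax) second allele
    p: np.ndarray            # (L, Kmax) frequencies, zero padded
    worker_ids: list
    locus_names: list
    allele_labels: list      # per locus, list of labels in index order


def encode_colony(table: GenotypeTable, freqs: AlleleFrequencies) -> EncodedColony:
    loci = table.locus_names
    for l, name in enumerate(loci):
        if name not in freqs.loci:
            raise ValueError(f"locus {name} absent from frequency table")
        extra = table.alleles_at(l) - set(freqs.labels(name))
        if extra:
            raise ValueError(
                f"locus {name}: alleles {sorted(extra)} absent from frequency table")
    L = len(loci)
    kvec = np.array([freqs.n_alleles(name) for name in loci], dtype=np.int64)
    if np.any(kvec < 2):
        bad = [loci[i] for i in np.where(kvec < 2)[0]]
        raise ValueError(f"loci with fewer than 2 alleles: {bad}")
    Kmax = int(kvec.max())
    nG = kvec * (kvec + 1) // 2
    Gmax = int(nG.max())
    ga = np.zeros((L, Gmax), dtype=np.int64)
    gb = np.zeros((L, Gmax), dtype=np.int64)
    p = np.zeros((L, Kmax))
    allele_labels = []
    for l, name in enumerate(loci):
        labels = freqs.labels(name)
        allele_labels.append(list(labels))
        k = kvec[l]
        p[l, :k] = freqs.p(name)
        g = 0
        for a in range(k):
            for b in range(a, k):
                ga[l, g] = a
                gb[l, g] = b
                g += 1

    def geno_index(entry, l):
        if entry is None:
            return -1
        labels = allele_labels[l]
        ia, ib = labels.index(entry[0]), labels.index(entry[1])
        return pair_index(ia, ib, int(kvec[l]))

    workers = table.worker_indices
    obs = np.full((len(workers), L), -1, dtype=np.int64)
    for row, i in enumerate(workers):
        for l in range(L):
            obs[row, l] = geno_index(table.entries[i][l], l)
    qobs = np.full(L, -1, dtype=np.int64)
    qi = table.queen_index
    if qi is not None:
        for l in range(L):
            qobs[l] = geno_index(table.entries[qi][l], l)
    return EncodedColony(obs, qobs, kvec, nG, ga, gb, p,
                         [table.individual_ids[i] for i in workers],
                         list(loci), allele_labels)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from one colony's joint posterior.

    ``partitions`` holds canonical (order-of-first-appearance) group labels
    per offspring; ``mothers`` is 0 for the queen, 1 for the latent drifter
    queen. ``queen_genotypes`` are triangular genotype indices per locus
    (decode with ``queen_genotype_labels``).
    """

    partitions: np.ndarray      # (S, n) int
    mothers: np.ndarray         # (S, n) int
    e1: np.ndarray              # (S,)
    e2: np.ndarray              # (S,)
    queen_genotypes: np.ndarray  # (S, L) int
    log_posterior: np.ndarray   # (S,) of retained sweeps
    trace: np.ndarray           # (sweeps,) per-sweep log posterior
    acceptance: dict
    config: SamplerConfig
    encoded: EncodedColony
    worker_ids: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.partitions.shape[0]

    @property
    def n_offspring(self) -> int:
        return self.partitions.shape[1]

    def queen_genotype_labels(self, sample: int):
        """Decode one sample's queen latent genotype into allele labels."""
        out = []
        enc = self.encoded
        for l, g in enumerate(self.queen_genotypes[sample]):
            a, b = enc.ga[l, g], enc.gb[l, g]
            out.append((enc.allele_labels[l][a], enc.allele_labels[l][b]))
        return out


def check_evaluable(table: GenotypeTable, min_polymorphic_loci: int = 6) -> int:
    """Count polymorphic loci and refuse colonies below the minimum."""
    n_poly = sum(len(table.alleles_at(l)) >= 2 for l in range(table.n_loci))
    if n_poly < min_polymorphic_loci:
        raise ColonyNotEvaluableError(
            f"colony not evaluable: {n_poly} polymorphic loci "
            f"(minimum {min_polymorphic_loci})", n_poly, min_polymorphic_loci)
    return n_poly


def run_sampler(table: GenotypeTable, freqs: AlleleFrequencies | None = None,
                config: SamplerConfig | None = None,
                min_polymorphic_loci: int = 6,
                log_path=None) -> PosteriorSamples:
    """Run the Gibbs sampler on one (QC-filtered) colony.

    When ``freqs`` is None, allele frequencies are estimated in-colony with
    add-one smoothing. Refuses colonies with fewer than
    ``min_polymorphic_loci`` polymorphic loci (set 0 to disable, e.g. for
    toy examples).
    """
    config = config or SamplerConfig()
    check_evaluable(table, min_polymorphic_loci)
    if freqs is None:
        freqs = estimate_allele_frequencies(table)
    enc = encode_colony(table, freqs)
    if enc.obs.shape[0] == 0:
        raise ValueError("colony has no workers")
    zs, moms, e1s, e2s, gmqs, ret_lp, trace, acc, steps = _kernel._run_chain(
        enc.obs, enc.qobs, enc.kvec, enc.nG, enc.ga, enc.gb, enc.p,
        float(config.alpha), float(config.drifter_prior),
        int(config.sweeps), int(config.burn_in), int(config.thin),
        int(config.seed), float(config.e1_init), float(config.e2_init),
        1 if config.fix_rates else 0, float(config.step),
        1 if config.queen_observed_with_error else 0)
    acceptance = {"e1": float(acc[0]), "e2": float(acc[1]),
                  "final_step_e1": float(steps[0]),
                  "final_step_e2": float(steps[1])}
    samples = PosteriorSamples(zs, moms, e1s, e2s, gmqs, ret_lp, trace,
                               acceptance, config, enc, enc.worker_ids)
    if log_path is not None:
        _write_log(log_path, samples)
    return samples


def _write_log(path, samples: PosteriorSamples) -> None:
    cfg = asdict(samples.config)
    with open(path, "w") as fh:
        fh.write("matefreq Gibbs sampler log\n")
        for key, val in cfg.items():
            fh.write(f"config {key} = {val}\n")
        fh.write(f"n_offspring = {samples.n_offspring}\n")
        fh.write(f"retained samples = {samples.n_samples}\n")
        for key, val in samples.acceptance.items():
            fh.write(f"{key} = {val:.4f}\n")
        tr = samples.trace
        fh.write("log-posterior trace (every 100th sweep):\n")
        for s in range(0, len(tr), 100):
            fh.write(f"  sweep {s}: {tr[s]:.3f}\n")
        fh.write(f"  sweep {len(tr) - 1}: {tr[-1]:.3f}\n")
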