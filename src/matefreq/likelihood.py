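"""Colony likelihood under a paternity partition, and the partition prior.

A colony is modeled as one queen (optionally a second, unobserved "drifter"
queen) whose offspring partition into full-sibling groups, one haploid father
per group. Loci are independent given the latent state. Conditional on the
queen's latent true genotype at a locus, a group's likelihood integrates the
shared father allele against population frequencies; each offspring draws one
maternal allele uniformly and the father's allele, and its observed genotype
is scored through the error model. The prior over full-sibling partitions is
a Dirichlet process with concentration ``alpha`` (Chinese restaurant
process).

These routines are the plain (slow) reference implementations used to encode
the model unambiguously; the Gibbs sampler runs compiled equivalents. They
also power the exact small-colony posterior (:func:`exact_partition_posterior`)
obtained by brute-force enumeration over set partitions and latent maternal
genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import gammaln

from .error_model import ErrorRates, genotype_pairs, observation_prob
from .genotypes import QUEEN, AlleleFrequencies, GenotypeTable


@dataclass
class PaternityState:
    """Latent state of the sampler for one colony.

    ``father_label[i]`` is an arbitrary group id for offspring ``i``;
    ``mother_indicator[i]`` is "queen" or "drifter". A father group never
    spans the two mothers. ``maternal_true_genotype`` and
    ``drifter_true_genotype`` hold one unordered allele pair per locus.
    """

    father_label: list
    mother_indicator: list
    maternal_true_genotype: list
    drifter_true_genotype: list = field(default_factory=list)
    rates: ErrorRates = ErrorRates(0.05, 0.05)

    def __post_init__(self):
        mother_of = {}
        for g, m in zip(self.father_label, self.mother_indicator):
            if mother_of.setdefault(g, m) != m:
                raise ValueError(f"father group {g!r} spans both mothers")

    def groups(self, mother=None):
        """Group label -> member offspring indices, optionally one mother's."""
        out: dict = {}
        for i, (g, m) in enumerate(zip(self.father_label,
                                       self.mother_indicator)):
            if mother is None or m == mother:
                out.setdefault(g, []).append(i)
        return out


def offspring_prob(observed, mother, father_allele, rates: ErrorRates,
                   k: int) -> float:
    """P(observed offspring genotype | maternal true genotype, father allele).

    The offspring inherits one of the mother's two alleles uniformly plus the
    father's allele; the observation is scored through the error model.
    """
    m1, m2 = mother
    return 0.5 * (observation_prob(observed, (m1, father_allele), rates, k)
                  + observation_prob(observed, (m2, father_allele), rates, k))


def group_marginal_likelihood(observations, mother, labels, p,
                              rates: ErrorRates, k: int) -> float:
    """Likelihood of one full-sib group's observations at one locus, with the
    shared father allele integrated against population frequencies.

    ``observations`` is an iterable of observed genotypes (pairs or None);
    ``labels``/``p`` are the locus's allele labels and frequencies. An empty
    group returns 1.
    """
    observations = list(observations)
    if not observations:
        return 1.0
    total = 0.0
    for a, pa in zip(labels, p):
        prod = pa
        for obs in observations:
            prod *= offspring_prob(obs, mother, a, rates, k)
            if prod == 0.0:
                break
        total += prod
    return total


def hwe_log_prior(genotype, labels, p) -> float:
    """Log Hardy-Weinberg probability of an unordered diploid genotype."""
    freq = dict(zip(labels, p))
    a, b = genotype
    if a == b:
        return 2.0 * math.log(freq[a])
    return math.log(2.0) + math.log(freq[a]) + math.log(freq[b])


def colony_log_likelihood(table: GenotypeTable, state: PaternityState,
                          freqs: AlleleFrequencies,
                          queen_observed_with_error: bool = True) -> float:
    """Joint log density of the observed colony data and the latent maternal
    genotypes, conditional on the paternity partition and error rates.

    Per locus: HWE log prior of the latent queen (and, if used, drifter)
    genotype, plus the queen's observation likelihood given her latent
    genotype, plus one integrated-father term per full-sib group. Summing
    ``exp`` of this over all latent maternal genotype combinations gives the
    partition marginal likelihood.
    """
    if not freqs.covers(table):
        unknown = set()
        for l, name in enumerate(table.locus_names):
            unknown |= table.alleles_at(l) - set(freqs.labels(name))
        raise ValueError(f"alleles absent from frequency table: {sorted(unknown)}")
    workers = table.worker_indices
    if len(state.father_label) != len(workers):
        raise ValueError("state size does not match number of workers")
    qi = table.queen_index
    use_drifter = "drifter" in state.mother_indicator
    rates = state.rates
    total = 0.0
    for l, name in enumerate(table.locus_names):
        labels, p = freqs.labels(name), freqs.p(name)
        k = len(labels)
        gm_q = state.maternal_true_genotype[l]
        total += hwe_log_prior(gm_q, labels, p)
        if qi is not None and queen_observed_with_error:
            total += _safe_log(
                observation_prob(table.entries[qi][l], gm_q, rates, k))
        mothers = [("queen", gm_q)]
        if use_drifter:
            gm_d = state.drifter_true_genotype[l]
            total += hwe_log_prior(gm_d, labels, p)
            mothers.append(("drifter", gm_d))
        for mother_name, gm in mothers:
            for members in state.groups(mother_name).values():
                obs = [table.entries[workers[i]][l] for i in members]
                total += _safe_log(
                    group_marginal_likelihood(obs, gm, labels, p, rates, k))
    return total


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0.0 else -math.inf


def crp_log_prior(partition, alpha: float) -> float:
    """Log probability of a set partition under the Chinese restaurant
    process with concentration ``alpha``.

    ``partition`` is a sequence of group labels, one per item. For K groups
    of sizes n_j over n items:
    ``alpha^K Gamma(alpha) / Gamma(alpha + n) * prod_j Gamma(n_j)``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    partition = list(partition)
    n = len(partition)
    if n < 1:
        raise ValueError("partition of at least one item required")
    sizes: dict = {}
    for g in partition:
        sizes[g] = sizes.get(g, 0) + 1
    lp = len(sizes) * math.log(alpha) + gammaln(alpha) - gammaln(alpha + n)
    for nj in sizes.values():
        lp += gammaln(nj)
    return float(lp)


# ---------------------------------------------------------------------------
# brute-force small-colony posterior


def set_partitions(n: int):
    """All set partitions of ``range(n)`` as label vectors in canonical
    (order-of-first-appearance) form. Bell(n) of them."""
    if n == 0:
        yield []
        return

    def rec(labels, next_label):
        i = len(labels)
        if i == n:
            yield list(labels)
            return
        for g in range(next_label + 1):
            labels.append(g)
            yield from rec(labels, max(next_label, g + 1))
            labels.pop()

    yield from rec([], 0)


def exact_partition_posterior(table: GenotypeTable, freqs: AlleleFrequencies,
                              rates: ErrorRates, alpha: float = 1.0,
                              queen_observed_with_error: bool = True):
    """Exact posterior over full-sib partitions of the workers, for small
    colonies, by enumeration.

    Marginalizes the queen's latent genotype and each group's father allele
    exactly (loci factorize). Drifters are excluded (single queen). Returns
    ``(partitions, probabilities)`` with partitions as canonical label
    tuples.

    Complexity is Bell(n) x loci x genotypes x alleles: intended for
    n <= ~7 workers.
    """
    workers = table.worker_indices
    n = len(workers)
    qi = table.queen_index
    parts = [tuple(p) for p in set_partitions(n)]
    log_w = []
    for part in parts:
        lp = crp_log_prior(part, alpha)
        groups: dict = {}
        for i, g in enumerate(part):
            groups.setdefault(g, []).append(i)
        for l, name in enumerate(table.locus_names):
            labels, p = freqs.labels(name), freqs.p(name)
            k = len(labels)
            locus_total = 0.0
            for gm in ((labels[a], labels[b]) for a, b in genotype_pairs(k)):
                term = math.exp(hwe_log_prior(gm, labels, p))
                qobs = None if qi is None else table.entries[qi][l]
                if qobs is not None and queen_observed_with_error:
                    term *= observation_prob(qobs, gm, rates, k)
                elif qobs is not None:
                    if tuple(sorted(gm)) != qobs:
                        continue
                    term = 1.0
                for members in groups.values():
                    obs = [table.entries[workers[i]][l] for i in members]
                    term *= group_marginal_likelihood(obs, gm, labels, p,
                                                      rates, k)
                    if term == 0.0:
                        break
                locus_total += term
            lp += _safe_log(locus_total)
        log_w.append(lp)
    log_w = np.array(log_w)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return parts, w / w.sum()
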