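"""Microsatellite genotyping-error model.

Observed genotypes are perturbed from true genotypes by two error classes,
with rates shared across loci within a colony:

* allelic dropout (``e1``): one allele of a heterozygote fails to amplify,
  so the genotype is scored as homozygous for the remaining allele;
* mistyping (``e2``): an allele copy is scored as a different allele,
  uniformly over the other ``k - 1`` alleles at the locus.

The generative composition is dropout first, then independent per-copy
mistyping. For a true heterozygote ``(a, b)``, with probability ``e1`` one of
the two alleles (chosen uniformly) drops and the intermediate genotype is the
survivor duplicated; homozygotes are unaffected by dropout. Each allele copy
of the intermediate genotype then mistypes independently with probability
``e2``. Both rates are bounded at 0.5 to keep the model identifiable.

A missing observation carries no information: its probability is 1 under any
true genotype (missingness is never treated as dropout evidence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ErrorRates:
    """Dropout and mistyping probabilities, global across loci in a colony."""

    e1: float
    e2: float

    def __post_init__(self):
        if not (0.0 <= self.e1 <= 0.5 and 0.0 <= self.e2 <= 0.5):
            raise ValueError(
                f"error rates must lie in [0, 0.5]: e1={self.e1}, e2={self.e2}")


def _mistype(u, v, e2: float, k: int) -> float:
    """P(copy u is scored as v)."""
    return 1.0 - e2 if u == v else e2 / (k - 1)


def observation_prob(observed, true, rates: ErrorRates, k: int) -> float:
    """P(observed unordered diploid genotype | true genotype).

    Parameters
    ----------
    observed : pair of allele labels, or None
        ``None`` (missing) returns 1.
    true : pair of allele labels
    rates : ErrorRates
    k : int
        Number of alleles in the locus universe (k >= 2).
    """
    if k < 2:
        raise ValueError("allele universe must have k >= 2")
    if not isinstance(rates, ErrorRates):
        rates = ErrorRates(*rates)
    if observed is None:
        return 1.0
    a, b = true
    x, y = observed
    e1, e2 = rates.e1, rates.e2
    # intermediate genotypes after the dropout stage, with weights
    if a == b:
        stages = ((a, b, 1.0),)
    else:
        stages = ((a, b, 1.0 - e1), (a, a, 0.5 * e1), (b, b, 0.5 * e1))
    total = 0.0
    for c, d, w in stages:
        if w == 0.0:
            continue
        if x == y:
            total += w * _mistype(c, x, e2, k) * _mistype(d, x, e2, k)
        else:
            total += w * (_mistype(c, x, e2, k) * _mistype(d, y, e2, k)
                          + _mistype(c, y, e2, k) * _mistype(d, x, e2, k))
    return total


def haploid_observation_prob(observed, true, e2: float, k: int) -> float:
    """P(a haploid allele is scored as ``observed`` given it is ``true``)."""
    if k < 2:
        raise ValueError("allele universe must have k >= 2")
    if not (0.0 <= e2 <= 0.5):
        raise ValueError("e2 must lie in [0, 0.5]")
    return 1.0 - e2 if observed == true else e2 / (k - 1)


def genotype_pairs(k: int):
    """All k(k+1)/2 unordered genotype index pairs (a <= b), in triangular
    row-major order: (0,0), (0,1), ..., (0,k-1), (1,1), ..."""
    return [(a, b) for a in range(k) for b in range(a, k)]


def pair_index(a: int, b: int, k: int) -> int:
    """Index of unordered pair (a, b) in :func:`genotype_pairs` order."""
    if a > b:
        a, b = b, a
    return a * k - (a * (a - 1)) // 2 + (b - a)


def observation_matrix(e1: float, e2: float, k: int) -> np.ndarray:
    """Dense matrix ``M[g_true, g_obs]`` of observation probabilities over all
    unordered genotypes at a k-allele locus, rows summing to 1."""
    rates = ErrorRates(e1, e2)
    pairs = genotype_pairs(k)
    n = len(pairs)
    out = np.empty((n, n))
    for i, t in enumerate(pairs):
        for j, o in enumerate(pairs):
            out[i, j] = observation_prob(o, t, rates, k)
    return out
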