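import math
from itertools import product

import numpy as np
import pytest
from scipy.special import gammaln

from matefreq import (AlleleFrequencies, ErrorRates, PaternityState,
                      colony_log_likelihood, crp_log_prior,
                      exact_partition_posterior, group_marginal_likelihood,
                      observation_prob, offspring_prob)
from matefreq.likelihood import set_partitions

from conftest import make_table

E0 = ErrorRates(0.0, 0.0)


class TestOffspringProb:
    def test_one_of_two_maternal_picks(self):
        assert offspring_prob(("1", "3"), ("1", "2"), "3", E0, 3) == 0.5

    def test_homozygous_mother_forced(self):
        assert offspring_prob(("1", "2"), ("1", "1"), "2", E0, 3) == 1.0

    def test_with_errors_matches_enumeration(self):
        # sum over the two maternal picks of the error-model probability
        rates = ErrorRates(0.1, 0.05)
        got = offspring_prob(("2", "2"), ("1", "2"), "1", rates, 4)
        expected = 0.5 * (observation_prob(("2", "2"), ("1", "1"), rates, 4)
                          + observation_prob(("2", "2"), ("2", "1"), rates, 4))
        assert got == pytest.approx(expected, abs=1e-14)
        assert got > 0


class TestGroupMarginal:
    def test_empty_group_is_one(self):
        assert group_marginal_likelihood([], ("1", "2"), ["1", "2"],
                                         [0.5, 0.5], E0, 2) == 1.0

    def test_single_offspring_hand_value(self):
        labels = ["1", "2", "3"]
        p = [1 / 3] * 3
        # only father allele 3 is compatible: (1/3) * (1/2)
        got = group_marginal_likelihood([("1", "3")], ("1", "2"),
                                        labels, p, E0, 3)
        assert got == pytest.approx(1 / 6)

    def test_never_exceeds_any_subset(self, rng):
        # each member contributes a factor <= 1 inside the father-allele sum,
        # so adding offspring can only shrink the group marginal
        labels = ["1", "2", "3"]
        p = np.array([0.5, 0.3, 0.2])
        rates = ErrorRates(0.05, 0.05)
        for _ in range(20):
            obs = [tuple(sorted(rng.choice(labels, 2))) for _ in range(3)]
            mother = tuple(sorted(rng.choice(labels, 2)))
            joint = group_marginal_likelihood(obs, mother, labels, p, rates, 3)
            for drop in range(3):
                subset = [o for j, o in enumerate(obs) if j != drop]
                sub = group_marginal_likelihood(subset, mother, labels, p,
                                                rates, 3)
                assert joint <= sub + 1e-12


class TestCRPPrior:
    def test_single_item(self):
        assert crp_log_prior([0], 1.0) == pytest.approx(0.0)

    def test_three_in_one_group(self):
        # sequential seating: (1/2)(2/3) = 1/3
        assert math.exp(crp_log_prior([0, 0, 0], 1.0)) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_normalizes_over_set_partitions(self, n, alpha):
        parts = list(set_partitions(n))
        total = sum(math.exp(crp_log_prior(p, alpha)) for p in parts)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_bell_numbers(self):
        assert [len(list(set_partitions(n))) for n in range(1, 7)] == \
            [1, 2, 5, 15, 52, 203]

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            crp_log_prior([0, 0], 0.0)


def _brute_force_marginal(table, partition, freqs, rates,
                          queen_observed_with_error=True):
    """Marginal likelihood of a partition by enumerating maternal genotypes
    and father alleles jointly per locus."""
    workers = table.worker_indices
    qi = table.queen_index
    groups = {}
    for i, g in enumerate(partition):
        groups.setdefault(g, []).append(i)
    total = 1.0
    for l, name in enumerate(table.locus_names):
        labels, p = freqs.labels(name), np.asarray(freqs.p(name))
        freq = dict(zip(labels, p))
        k = len(labels)
        locus = 0.0
        for m1, m2 in product(labels, repeat=2):
            term = freq[m1] * freq[m2]  # ordered HWE
            if qi is not None and queen_observed_with_error:
                term *= observation_prob(table.entries[qi][l], (m1, m2),
                                         rates, k)
            for members in groups.values():
                g_term = 0.0
                for fa in labels:
                    prod = freq[fa]
                    for i in members:
                        obs = table.entries[workers[i]][l]
                        # offspring inherits m1 or m2 with prob 1/2 each
                        prod *= 0.5 * (
                            observation_prob(obs, (m1, fa), rates, k)
                            + observation_prob(obs, (m2, fa), rates, k))
                    g_term += prod
                term *= g_term
            locus += term
        total *= locus
    return total


class TestColonyLogLikelihood:
    def _toy(self):
        table = make_table([[("1", "2")], [("1", "3")]],
                           queen=[("1", "2")], loci=["L1"])
        freqs = AlleleFrequencies({"L1": (["1", "2", "3"],
                                          [0.5, 0.3, 0.2])})
        return table, freqs

    def test_all_missing_offspring_contributes_nothing(self):
        table = make_table([[("1", "2")], [None]], queen=[("1", "2")],
                           loci=["L1"])
        freqs = AlleleFrequencies({"L1": (["1", "2"], [0.5, 0.5])})
        state2 = PaternityState([0, 1], ["queen", "queen"],
                                [("1", "2")], rates=E0)
        state1 = PaternityState([0], ["queen"], [("1", "2")], rates=E0)
        sub = table.subset(individuals=[0, 1])
        ll2 = colony_log_likelihood(table, state2, freqs)
        ll1 = colony_log_likelihood(sub, state1, freqs)
        assert ll2 == pytest.approx(ll1, abs=1e-12)

    @pytest.mark.parametrize("partition", [(0, 0), (0, 1)])
    def test_summing_latent_genotypes_matches_brute_force(self, partition):
        # exp(joint log density) summed over all maternal genotypes equals
        # the enumerated marginal likelihood of the partition
        table, freqs = self._toy()
        rates = ErrorRates(0.1, 0.05)
        labels = freqs.labels("L1")
        total = 0.0
        for a, b in product(labels, repeat=2):
            if a > b:
                continue
            state = PaternityState(list(partition), ["queen", "queen"],
                                   [(a, b)], rates=rates)
            total += math.exp(colony_log_likelihood(table, state, freqs))
        expected = _brute_force_marginal(table, partition, freqs, rates)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_offspring_and_label_permutation(self):
        table, freqs = self._toy()
        rates = ErrorRates(0.05, 0.05)
        s1 = PaternityState([0, 1], ["queen", "queen"], [("1", "2")],
                            rates=rates)
        s2 = PaternityState([7, 3], ["queen", "queen"], [("1", "2")],
                            rates=rates)
        assert colony_log_likelihood(table, s1, freqs) == pytest.approx(
            colony_log_likelihood(table, s2, freqs))
        flipped = table.subset(individuals=[0, 2, 1])
        s3 = PaternityState([1, 0], ["queen", "queen"], [("1", "2")],
                            rates=rates)
        assert colony_log_likelihood(flipped, s3, freqs) == pytest.approx(
            colony_log_likelihood(table, s1, freqs))

    def test_unknown_allele_rejected(self):
        table, _ = self._toy()
        freqs = AlleleFrequencies({"L1": (["1", "2"], [0.5, 0.5])})
        state = PaternityState([0, 0], ["queen", "queen"], [("1", "2")],
                               rates=E0)
        with pytest.raises(ValueError, match="absent"):
            colony_log_likelihood(table, state, freqs)

    def test_groups_cannot_span_mothers(self):
        with pytest.raises(ValueError, match="spans"):
            PaternityState([0, 0], ["queen", "drifter"], [("1", "2")])


class TestExactPartitionPosterior:
    def test_matches_independent_brute_force(self):
        table = make_table([[("1", "2"), ("2", "3")],
                            [("1", "3"), ("1", "1")],
                            [("2", "2"), ("1", "2")]],
                           queen=[("1", "2"), ("1", "2")])
        freqs = AlleleFrequencies.uniform(["L1", "L2"], 3)
        rates = ErrorRates(0.05, 0.05)
        parts, probs = exact_partition_posterior(table, freqs, rates, alpha=1.0)
        assert probs.sum() == pytest.approx(1.0)
        raw = np.array([
            math.exp(crp_log_prior(p, 1.0))
            * _brute_force_marginal(table, p, freqs, rates) for p in parts])
        assert np.allclose(probs, raw / raw.sum(), atol=1e-12)
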