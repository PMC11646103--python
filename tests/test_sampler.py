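import numpy as np
import pytest

from matefreq import (AlleleFrequencies, ColonyNotEvaluableError, ErrorRates,
                      SamplerConfig, SimulationSpec, exact_partition_posterior,
                      run_sampler, simulate_colony, summarize)

from conftest import make_table


def _empirical_partition_freqs(samples):
    out = {}
    for row in samples.partitions:
        key = tuple(row)
        out[key] = out.get(key, 0) + 1
    return {k: v / samples.n_samples for k, v in out.items()}


def total_variation(exact: dict, empirical: dict) -> float:
    keys = set(exact) | set(empirical)
    return 0.5 * sum(abs(exact.get(k, 0.0) - empirical.get(k, 0.0))
                     for k in keys)


class TestExactnessOnSmallColonies:
    def test_partition_distribution_matches_enumeration(self, rng):
        """Gibbs partition frequencies agree with the exact enumerated
        posterior on small colonies with fixed rates and observed queen."""
        worst = 0.0
        for trial in range(3):
            spec = SimulationSpec(n_loci=2, alleles_per_locus=3,
                                  n_offspring=4,
                                  n_fathers=int(rng.integers(1, 3)),
                                  e1=0.05, e2=0.05,
                                  seed=int(rng.integers(2 ** 30)))
            table, _ = simulate_colony(spec)
            freqs = spec.frequency_model()
            parts, probs = exact_partition_posterior(
                table, freqs, ErrorRates(0.05, 0.05), alpha=1.0)
            cfg = SamplerConfig(sweeps=20000, burn_in=2000, thin=1,
                                seed=trial, drifter_prior=0.0,
                                fix_rates=True, e1_init=0.05, e2_init=0.05)
            samples = run_sampler(table, freqs, cfg, min_polymorphic_loci=0)
            tv = total_variation(dict(zip(parts, probs)),
                                 _empirical_partition_freqs(samples))
            worst = max(worst, tv)
        assert worst < 0.05

    def test_incompatible_offspring_never_share_a_father(self):
        # at e=0 two offspring whose paternal contributions cannot come from
        # one haploid father are never grouped
        table = make_table([[("1", "3"), ("1", "3")],
                            [("2", "2"), ("2", "2")]],
                           queen=[("1", "2"), ("1", "2")])
        freqs = AlleleFrequencies.uniform(["L1", "L2"], 3)
        cfg = SamplerConfig(sweeps=2000, burn_in=500, thin=1, seed=1,
                            drifter_prior=0.0, fix_rates=True,
                            e1_init=0.0, e2_init=0.0)
        samples = run_sampler(table, freqs, cfg, min_polymorphic_loci=0)
        assert np.all(samples.partitions[:, 0] != samples.partitions[:, 1])

    def test_single_offspring_always_one_group(self):
        table = make_table([[("1", "2")] * 6], queen=[("1", "1")] * 6)
        cfg = SamplerConfig(sweeps=500, burn_in=100, thin=1, seed=0)
        samples = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        assert np.all(samples.partitions == 0)


class TestPlantedTruthRecovery:
    @pytest.mark.parametrize("k_true", [1, 2])
    def test_zero_error_modal_father_count(self, k_true):
        spec = SimulationSpec(n_loci=8, n_fathers=k_true, e1=0.0, e2=0.0,
                              seed=42 + k_true)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=3000, burn_in=1000, thin=2, seed=7,
                            drifter_prior=0.0)
        summ = summarize(run_sampler(table, spec.frequency_model(), cfg,
                                     min_polymorphic_loci=0))
        assert summ.map_k == k_true
        assert summ.p_fathers[k_true] > 0.9

    def test_rates_shrink_on_error_free_data(self):
        means = []
        for rep in range(6):
            spec = SimulationSpec(n_fathers=1, e1=0.0, e2=0.0, seed=100 + rep)
            table, _ = simulate_colony(spec)
            cfg = SamplerConfig(sweeps=3000, burn_in=1000, thin=2, seed=rep,
                                drifter_prior=0.0)
            summ = summarize(run_sampler(table, spec.frequency_model(), cfg,
                                         min_polymorphic_loci=0))
            means.append(max(summ.e1_mean, summ.e2_mean))
        assert np.median(means) < 0.02

    def test_unobserved_queen_genotype_recovered(self):
        # with enough error-free offspring the queen's latent genotype is
        # pinned by her offspring alone
        spec = SimulationSpec(n_loci=6, n_fathers=1, e1=0.0, e2=0.0,
                              queen_observed=False, seed=11)
        table, truth = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=2000, burn_in=500, thin=2, seed=3,
                            drifter_prior=0.0, fix_rates=True,
                            e1_init=0.0, e2_init=0.0)
        samples = run_sampler(table, spec.frequency_model(), cfg,
                              min_polymorphic_loci=0)
        modal = []
        for l in range(6):
            vals, counts = np.unique(samples.queen_genotypes[:, l],
                                     return_counts=True)
            modal.append(vals[np.argmax(counts)])
        decoded = samples.queen_genotype_labels(0)
        # compare the modal genotype of the final locus-wise chain to truth
        enc = samples.encoded
        got = [tuple(sorted((enc.allele_labels[l][enc.ga[l, g]],
                             enc.allele_labels[l][enc.gb[l, g]])))
               for l, g in enumerate(modal)]
        want = [tuple(sorted(x)) for x in truth["queen_genotype"]]
        for l, (g, w) in enumerate(zip(got, want)):
            if g == w:
                continue
            # a homozygous queen whose offspring all share one genotype
            # (a, b) is not identifiable from the mirrored (b, b) + father a
            obs = {table.entries[i][l] for i in table.worker_indices}
            assert w[0] == w[1] and len(obs) == 1
            a, b = next(iter(obs))
            assert g in ((a, a), (b, b))
        assert len(decoded) == 6


class TestMechanics:
    def test_seed_reproducibility(self):
        spec = SimulationSpec(n_fathers=2, e1=0.05, e2=0.05, seed=5)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=600, burn_in=100, thin=2, seed=9)
        a = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        b = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        assert np.array_equal(a.partitions, b.partitions)
        assert np.array_equal(a.e1, b.e1) and np.array_equal(a.e2, b.e2)
        assert np.array_equal(a.trace, b.trace)

    @pytest.mark.parametrize("sweeps,burn,thin,expect",
                             [(1200, 200, 10, 100), (1001, 0, 10, 100),
                              (650, 100, 7, 78)])
    def test_retained_count(self, sweeps, burn, thin, expect):
        spec = SimulationSpec(n_loci=3, n_offspring=4, seed=1)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=sweeps, burn_in=burn, thin=thin, seed=0)
        samples = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        assert samples.n_samples == expect == cfg.n_retained

    def test_rates_stay_in_bounds(self):
        spec = SimulationSpec(n_fathers=1, e1=0.1, e2=0.1, seed=2)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=800, burn_in=200, thin=1, seed=0)
        samples = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        for arr in (samples.e1, samples.e2):
            assert np.all((arr > 0) & (arr < 0.5))

    def test_refuses_non_evaluable_colony(self):
        table = make_table([[("1", "2")] * 3, [("1", "3")] * 3])
        with pytest.raises(ColonyNotEvaluableError, match="polymorphic"):
            run_sampler(table, None, SamplerConfig(sweeps=10, burn_in=0))

    def test_canonical_labels_order_of_first_appearance(self):
        spec = SimulationSpec(n_fathers=3, e1=0.0, e2=0.0, seed=8)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=600, burn_in=100, thin=2, seed=4,
                            drifter_prior=0.0)
        samples = run_sampler(table, None, cfg, min_polymorphic_loci=0)
        for row in samples.partitions:
            seen = []
            for g in row:
                if g not in seen:
                    seen.append(g)
            assert seen == list(range(len(seen)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(alpha=0.0)
        with pytest.raises(ValueError):
            SamplerConfig(drifter_prior=0.5)
        with pytest.raises(ValueError):
            SamplerConfig(sweeps=100, burn_in=100)

    def test_log_written(self, tmp_path):
        spec = SimulationSpec(n_loci=3, n_offspring=4, seed=1)
        table, _ = simulate_colony(spec)
        cfg = SamplerConfig(sweeps=300, burn_in=100, thin=2, seed=0)
        run_sampler(table, None, cfg, min_polymorphic_loci=0,
                    log_path=tmp_path / "run.log")
        text = (tmp_path / "run.log").read_text()
        assert "log-posterior trace" in text and "config alpha" in text
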