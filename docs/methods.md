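# Methods

## Model

One colony at a time. Data are unordered diploid genotypes at L
microsatellite loci for N workers and, optionally, the queen; entries may
be missing. Population allele frequencies p_a per locus come from a
reference table or, failing that, in-colony counts with add-one smoothing.

**Inheritance.** Males are haploid. A full-sib group shares one father,
whose single allele per locus is a latent draw from p_a (independent across
loci — no linkage). A worker inherits one of its mother's two alleles
uniformly at random plus the father's allele. The queen's true genotype per
locus is latent with a Hardy–Weinberg prior under p_a.

**Observation (error) model.** Observed genotypes are the truth perturbed
by two error classes with rates shared across loci within a colony:

1. dropout ε₁ ∈ [0, 0.5]: a heterozygote loses one allele (chosen
   uniformly) with probability ε₁ and is scored homozygous for the
   survivor; homozygotes are unaffected;
2. mistyping ε₂ ∈ [0, 0.5]: each allele copy of the post-dropout genotype
   is independently rescored with probability ε₂, uniformly over the other
   k − 1 alleles of the locus.

Composition order is dropout then mistyping. Both-allele dropout is treated
as missing data upstream, not as an error event, and a missing observation
has likelihood 1 under every true genotype (missingness is never dropout
evidence). The 0.5 bounds keep the rates identifiable. The model is pinned
by an exhaustive path-enumeration oracle in the test suite rather than by a
closed-form citation; mistyping is uniform (no size-ladder bias) as the
simplest model consistent with "an allele scored as another allele".

**Partition prior.** Full-sib groups follow a Dirichlet process with
concentration α (default 1.0, exposed in `SamplerConfig`; no hyperprior).
Under the Chinese-restaurant form a partition of n workers into K groups of
sizes n_j has probability α^K Γ(α) Γ(n_j)… / Γ(α + n).

**Drifters.** A single latent second queen (Hardy–Weinberg genotype, never
observed) carries its own father groups under the same partition machinery;
groups never span the two mothers. Each worker is a priori a drifter with
probability d (default 0.05); d = 0 disables the machinery. Queens of
different colonies are assumed unrelated.

**Likelihood.** Conditional on the partition, mothers' latent genotypes and
rates, loci are independent; a group's likelihood at a locus integrates the
shared father allele: Σ_a p_a Π_i [½ Σ_m P(obs_i | (m, a))] with the inner
sum over the mother's two alleles and P the error model. The queen's
observed genotype enters as P(obs_queen | latent genotype) (toggleable; an
observed queen can instead be taken as exact).

## Sampler

Gibbs sweeps over three blocks:

1. **Partition.** For each worker in turn, remove it and reassign among:
   each existing group j with weight n_j × (group marginal with it / group
   marginal without it) × mother prior; a new group under the queen or the
   drifter with weight α × singleton marginal × mother prior. Log-space
   throughout.
2. **Maternal genotypes.** Each mother's latent genotype per locus is drawn
   from its exact full conditional by enumerating all k(k+1)/2 genotypes
   (HWE prior × queen observation × attached group marginals).
3. **Error rates.** No conjugate update exists through the
   father-marginalized likelihood, so ε₁ and ε₂ are updated separately by
   Metropolis with a Gaussian random walk on logit(ε/0.5) (initial step
   0.3, multiplicatively adapted every 50 burn-in sweeps toward 20–50%
   acceptance; uniform prior and logit Jacobian in the ratio).

Initialization: all workers one group under the queen, rates 0.05, maternal
genotypes drawn from their conditionals. Defaults: 12,000 sweeps, 2,000
burn-in, thinning 10 → 1,000 retained samples. Retained partitions are
relabeled canonically (order of first appearance) so summaries are
label-invariant. All randomness flows from a single integer seed; identical
input + config + seed gives identical output. The inner loops are compiled
with numba; a plain-Python reference implementation of every likelihood
piece lives in `likelihood.py` and the two are pinned together by tests.

Correctness is checked by brute force: for small colonies the partition
posterior is computed exactly by enumerating all set partitions and
latent maternal genotypes (`exact_partition_posterior`), and the sampler's
partition frequencies agree within total-variation 0.05 (typically ~0.005).

## Summaries

Per retained sample, the number of fathers K and m_e = 1/Σ p_i² are
computed from the full-sib group sizes among queen-assigned workers only
(drifters excluded); `p_fathers` is the frequency of K over samples, `m_e`
the mean of per-sample values (computing m_e from averaged proportions is
also exposed but is not the default, since averaging the statistic matches
per-sample uncertainty propagation). The modal K breaks ties toward fewer
fathers. Paternity proportions are averaged over the modal-K samples after
sorting groups by size (largest = father 1); true sire proportions among
*unsampled* brood are unobservable. Across colonies the mean and sample
standard deviation of m_e are reported with a tally of modal father counts.
The reported "±" value is an SD over colonies, and is labeled as such.

## Quality control

Before inference: workers missing >50% of loci are discarded, then loci
missing in >50% of individuals, then loci monomorphic within the colony.
The queen is always kept (her genotype is optional side data, not a sampled
offspring, and the individual-level rule is stated for workers). This
individual→locus→monomorphic order maximizes retained loci; both thresholds
are configurable. A colony is evaluable only with ≥6 polymorphic loci
(≥2 alleles observed in-colony); the sampler refuses otherwise. Missing
filters are applied before inference, hence before drifter identification.

## Simulator

`simulate_colony` draws the queen from HWE, each father from p_a, offspring
by Mendelian inheritance, then pushes every genotype (including the
queen's) through the generative error model and masks entries at a given
missing rate. Drifters are offspring of a second simulated queen and their
own random sires. The default skew rule gives every father beyond the first
exactly one of the 20 offspring — the hardest configuration for separating
minority fathers from genotyping error. The default frequency model when no
reference table is supplied is 11 loci × 5 equally frequent alleles, a
deliberately conservative stand-in for a real reference population (real
microsatellite panels are typically more polymorphic and unequal).

What the simulator does *not* emulate: null alleles, size-ladder-adjacent
mistyping, per-locus rate variation, relatedness between queens, inbreeding
or population structure. Passing the power tests therefore demonstrates
correctness of the inference machinery under the stated model, not
robustness to these real-data features.

## Power analysis

Two grids, each cell = simulate-then-fit replicates with both rates free:

- father grid: true K = 1–6 × ε = 0.01/0.05/0.1 (both classes), 11 loci ×
  5 equal alleles;
- loci grid: 2/4/8/16 loci of 3 equal alleles at ε = 0.05.

The reported accuracy matrix holds the average posterior vector over the
number of fathers per cell (columns sum to 1; counts above 8 fold into the
last bin, where they carry essentially no mass). Inside simulation studies
the sampler runs a lighter schedule — 3,000 sweeps, 1,000 burn-in, thinning
2, still 1,000 retained — and drifter modeling is off, since simulated
colonies contain no drifters; spot checks against the full 12,000-sweep
schedule gave indistinguishable accuracy. The packaged validation uses 50
replicates per cell (the grids accept any count). Per-replicate seeds
derive from one root seed through `numpy.random.SeedSequence`, so grids are
reproducible and parallelizable.

Drifter-detection checks use 8 loci × 10 equally frequent alleles,
representative of the highly polymorphic panels used for drifter screening.
This matters: with 5-allele loci, roughly 15% of truly unrelated workers
are Mendelian-compatible with the queen at nearly every locus, and their
*exact* posterior drifter probability is genuinely intermediate — more loci
or more alleles, not more sweeps, is the remedy.

## Numerical choices and degenerate inputs

- Zero-likelihood candidates (possible only at ε = 0) get weight −∞; if
  every candidate is impossible the worker falls back to a fresh group
  under the queen (unreachable from a consistent state).
- Allele labels are compared after zero-padding normalization ("098" ≡
  "98"); pairs are stored unordered.
- With an unobserved queen and a monandrous, locus-wise-identical brood,
  the mother/father homozygote assignment is not identifiable (queen (a,a)
  + sire b mirrors queen (b,b) + sire a); the posterior correctly splits
  between the two.
- Retained-sample count is exactly floor((sweeps − burn_in)/thin).

## Limitations

- Rates are global across loci within a colony; per-locus rates and null
  alleles are out of scope.
- One latent drifter queen: multiple unrelated source colonies are merged
  into it (flags remain valid, drifter sib-structure is not interpreted).
- No split-merge moves; mixing over partitions relies on single-worker
  moves, which is adequate at colony sizes (~10–30 workers) but untested
  for hundreds of offspring.
- Exact enumeration cross-checks are feasible only for ≤ ~7 workers.
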