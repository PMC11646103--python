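"""Scikit-learn-style estimator wrapping QC, sampling, and summarization.

``ColonyPaternity`` behaves like a clustering estimator: ``fit`` takes one
colony's :class:`~matefreq.genotypes.GenotypeTable`, runs the Gibbs sampler,
and exposes the posterior through fitted attributes (``labels_`` is the
highest-posterior sampled partition of the workers). It composes with
``sklearn.base.clone`` and ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import AlleleFrequencies, GenotypeTable, qc_filter
from .sampler import SamplerConfig, run_sampler
from .summaries import summarize


class ColonyPaternity(BaseEstimator):
    """Joint Bayesian inference of paternity partition and genotyping error
    for one haplodiploid colony.

    Parameters
    ----------
    alpha : float, Dirichlet-process concentration over full-sib groups.
    drifter_prior : float, prior probability an offspring descends from a
        latent second (unobserved) queen; 0 disables drifter detection.
    sweeps, burn_in, thin : Gibbs schedule (default retains 1,000 samples).
    queen_observed_with_error : treat an observed queen genotype as
        error-prone data rather than ground truth.
    e1_init, e2_init : starting (or, with ``fix_rates``, fixed) dropout and
        mistyping rates.
    fix_rates : bool, hold error rates at their initial values.
    apply_qc : bool, run the colony QC filters before inference.
    max_missing_frac, min_polymorphic_loci : QC thresholds.
    random_state : int seed.

    Attributes (after ``fit``)
    --------------------------
    samples_ : PosteriorSamples
    summary_ : PosteriorSummary
    labels_ : ndarray, MAP-sample full-sib group label per retained worker
    p_fathers_ : dict, posterior over the number of fathers
    map_k_ : int, modal number of fathers
    m_e_ : float, posterior-mean effective mating frequency
    drifter_flags_ : dict, per-worker posterior drifter probability
    e1_, e2_ : float, posterior-mean error rates
    qc_report_ : QCReport
    """

    def __init__(self, alpha=1.0, drifter_prior=0.05, sweeps=12000,
                 burn_in=2000, thin=10, queen_observed_with_error=True,
                 e1_init=0.05, e2_init=0.05, fix_rates=False, step=0.3,
                 apply_qc=True, max_missing_frac=0.5, min_polymorphic_loci=6,
                 random_state=0):
        self.alpha = alpha
        self.drifter_prior = drifter_prior
        self.sweeps = sweeps
        self.burn_in = burn_in
        self.thin = thin
        self.queen_observed_with_error = queen_observed_with_error
        self.e1_init = e1_init
        self.e2_init = e2_init
        self.fix_rates = fix_rates
        self.step = step
        self.apply_qc = apply_qc
        self.max_missing_frac = max_missing_frac
        self.min_polymorphic_loci = min_polymorphic_loci
        self.random_state = random_state

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            alpha=self.alpha, drifter_prior=self.drifter_prior,
            sweeps=self.sweeps, burn_in=self.burn_in, thin=self.thin,
            seed=self.random_state,
            queen_observed_with_error=self.queen_observed_with_error,
            e1_init=self.e1_init, e2_init=self.e2_init,
            fix_rates=self.fix_rates, step=self.step)

    def fit(self, X: GenotypeTable, y=None, freqs: AlleleFrequencies | None = None):
        """Run QC (optionally) and the Gibbs sampler on one colony.

        ``freqs`` supplies reference-population allele frequencies; when
        absent they are estimated in-colony with add-one smoothing.
        """
        if not isinstance(X, GenotypeTable):
            raise TypeError("X must be a GenotypeTable")
        if self.apply_qc:
            table, report = qc_filter(X, self.max_missing_frac,
                                      self.min_polymorphic_loci)
        else:
            table, report = X, None
        self.qc_report_ = report
        self.samples_ = run_sampler(
            table, freqs, self._config(),
            min_polymorphic_loci=self.min_polymorphic_loci if self.apply_qc else 0)
        self.summary_ = summarize(self.samples_)
        self.p_fathers_ = self.summary_.p_fathers
        self.map_k_ = self.summary_.map_k
        self.m_e_ = self.summary_.m_e
        self.drifter_flags_ = self.summary_.drifter_flags
        self.e1_ = self.summary_.e1_mean
        self.e2_ = self.summary_.e2_mean
        best = int(np.argmax(self.samples_.log_posterior))
        self.labels_ = self.samples_.partitions[best].copy()
        self.worker_ids_ = list(self.samples_.worker_ids)
        return self

    def fit_summarize(self, X, freqs=None, colony_id="colony"):
        """Fit and return the colony's PosteriorSummary with an id attached."""
        self.fit(X, freqs=freqs)
        self.summary_.colony_id = colony_id
        return self.summary_
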