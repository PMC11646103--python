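"""Posterior summaries: number of fathers, paternity proportions, effective
mating frequency, drifter flags, and error-rate estimates.

The effective mating frequency is Starr's ``m_e = 1 / sum(p_i^2)`` where
``p_i`` is the proportion of sampled offspring sired by father ``i``. It is
computed per retained posterior sample from that sample's full-sib group
sizes among the queen's own offspring (drifter-assigned offspring are
excluded) and then averaged over samples; a monandrous colony has
``m_e = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples


def effective_mating_frequency(proportions) -> float:
    """Starr's effective number of matings, ``1 / sum(p_i^2)``.

    ``proportions`` must be nonnegative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(proportions, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {p.sum()})")
    return float(1.0 / np.sum(p ** 2))


@dataclass
class PosteriorSummary:
    """Reported quantities for one colony."""

    colony_id: str
    p_fathers: dict                 # K -> posterior probability
    map_k: int
    paternity_proportions: np.ndarray  # posterior-mean p_i at the MAP K
    m_e: float                      # mean over per-sample m_e
    m_e_sd: float
    m_e_from_mean_proportions: float
    drifter_flags: dict             # worker id -> P(drifter)
    e1_mean: float
    e2_mean: float
    n_offspring_used: int
    n_samples: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def n_drifters(self) -> int:
        """Workers more likely drifter than queen offspring."""
        return sum(v > 0.5 for v in self.drifter_flags.values())

    def to_dict(self) -> dict:
        return {
            "colony_id": self.colony_id,
            "p_fathers": {int(k): float(v) for k, v in self.p_fathers.items()},
            "map_k": int(self.map_k),
            "paternity_proportions": [float(x) for x in self.paternity_proportions],
            "m_e": float(self.m_e),
            "m_e_sd": float(self.m_e_sd),
            "m_e_from_mean_proportions": float(self.m_e_from_mean_proportions),
            "drifter_flags": {k: float(v) for k, v in self.drifter_flags.items()},
            "n_drifters": int(self.n_drifters),
            "e1_mean": float(self.e1_mean),
            "e2_mean": float(self.e2_mean),
            "n_offspring_used": int(self.n_offspring_used),
            "n_samples": int(self.n_samples),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _sample_counts_and_me(samples: PosteriorSamples):
    """Per-sample father-group count and m_e among queen-assigned offspring."""
    S = samples.n_samples
    ks = np.zeros(S, dtype=int)
    mes = np.full(S, np.nan)
    for s in range(S):
        mask = samples.mothers[s] == 0
        if not mask.any():
            continue
        labels = samples.partitions[s][mask]
        sizes = np.bincount(labels)
        sizes = sizes[sizes > 0].astype(float)
        ks[s] = len(sizes)
        props = sizes / sizes.sum()
        mes[s] = 1.0 / np.sum(props ** 2)
    return ks, mes


def summarize(samples: PosteriorSamples, colony_id: str = "colony") -> PosteriorSummary:
    """Turn posterior samples into the colony's reported quantities.

    Per retained sample, father groups are counted among queen-assigned
    offspring only, and that sample's m_e is computed from its group sizes;
    ``p_fathers`` is the relative frequency of counts, ``m_e`` their mean.
    Paternity proportions are averaged over the samples whose count equals
    the maximum-a-posteriori K, matching groups by size rank (largest group
    = father 1). MAP ties break toward smaller K (parsimony).
    """
    if samples.n_samples == 0:
        raise ValueError("no retained samples")
    ks, mes = _sample_counts_and_me(samples)
    valid = ks > 0
    if not valid.any():
        raise ValueError("no sample assigns any offspring to the queen")
    kvals, counts = np.unique(ks[valid], return_counts=True)
    p_fathers = {int(k): float(c / valid.sum()) for k, c in zip(kvals, counts)}
    map_k = int(max(p_fathers, key=lambda k: (p_fathers[k], -k)))
    sel = valid & (ks == map_k)
    props = np.zeros(map_k)
    for s in np.where(sel)[0]:
        mask = samples.mothers[s] == 0
        labels = samples.partitions[s][mask]
        sizes = np.bincount(labels)
        sizes = np.sort(sizes[sizes > 0])[::-1].astype(float)
        props += sizes / sizes.sum()
    props /= sel.sum()
    flags = {}
    for j, wid in enumerate(samples.worker_ids):
        flags[wid] = float(np.mean(samples.mothers[:, j] == 1))
    m_e = float(np.mean(mes[valid]))
    m_e_sd = float(np.std(mes[valid]))
    m_e_alt = effective_mating_frequency(props / props.sum())
    n_used = sum(v <= 0.5 for v in flags.values())
    return PosteriorSummary(
        colony_id=colony_id,
        p_fathers=p_fathers,
        map_k=map_k,
        paternity_proportions=props,
        m_e=m_e,
        m_e_sd=m_e_sd,
        m_e_from_mean_proportions=m_e_alt,
        drifter_flags=flags,
        e1_mean=float(np.mean(samples.e1)),
        e2_mean=float(np.mean(samples.e2)),
        n_offspring_used=n_used,
        n_samples=samples.n_samples,
    )


def aggregate_colonies(summaries):
    """Across-colony mean and SD of m_e plus a tally of modal father counts.

    The SD is the sample standard deviation over colonies (the "± value"
    reported alongside the mean).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to aggregate")
    mes = np.array([s.m_e for s in summaries])
    counts: dict = {}
    for s in summaries:
        counts[s.map_k] = counts.get(s.map_k, 0) + 1
    sd = float(np.std(mes, ddof=1)) if len(mes) > 1 else 0.0
    return float(np.mean(mes)), sd, dict(sorted(counts.items()))


def summaries_to_frame(summaries, k_max: int = 6) -> pd.DataFrame:
    """One row per colony: map_K, p_fathers columns K1..K{k_max}, m_e,
    error-rate means, and the drifter count."""
    rows = []
    for s in summaries:
        row = {"colony_id": s.colony_id, "map_K": s.map_k}
        for k in range(1, k_max + 1):
            row[f"K{k}"] = s.p_fathers.get(k, 0.0)
        row["m_e"] = s.m_e
        row["e1_mean"] = s.e1_mean
        row["e2_mean"] = s.e2_mean
        row["n_drifters"] = s.n_drifters
        rows.append(row)
    return pd.DataFrame(rows)
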