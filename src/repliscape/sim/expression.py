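"""Negative-binomial timecourse expression simulator.

Counts for gene *g* in sample *j* follow NB with mean
``baseline_g * size_factor_j * 2^effect`` where the effect is the gene's
cluster trajectory evaluated at the sample's timepoint, applied in the
treatment condition only, and variance ``mu + dispersion * mu^2``
(gamma-Poisson mixture; dispersion 0 is exactly Poisson). Effects are 0
at the G1 timepoint for every cluster, so all strain differences arise
after release, matching the timecourse-test design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..annotation import GenomeAnnotation
from ..expression import CountMatrix

__all__ = ["ExpressionSimConfig", "simulate_expression_counts"]


def _default_trajectories(
    timepoints: np.ndarray, n_clusters: int, effect_size: float
) -> np.ndarray:
    """(n_clusters, n_timepoints) log2 effects: Gaussian bumps of
    alternating sign whose centres tile the timecourse; exactly 0 at t=0."""
    span = timepoints[-1] - timepoints[0]
    centers = timepoints[0] + span * (np.arange(n_clusters) + 1.5) / (n_clusters + 2)
    width = span / 6.0
    eff = np.empty((n_clusters, len(timepoints)))
    for c in range(n_clusters):
        sign = 1.0 if c % 2 == 0 else -1.0
        eff[c] = sign * effect_size * np.exp(-0.5 * ((timepoints - centers[c]) / width) ** 2)
    eff[:, timepoints == timepoints[0]] = 0.0
    return eff


@dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    timepoints: tuple[float, ...] = tuple(range(0, 65, 5))
    n_replicates: int = 2
    conditions: tuple[str, str] = ("control", "treatment")
    baseline_mean: float = 200.0
    baseline_log_sd: float = 0.8  # lognormal spread of per-gene baselines
    dispersion: float = 0.05
    n_clusters: int = 6
    frac_de: float = 0.27
    effect_size: float = 2.0  # peak |log2 fold-change| of cluster trajectories
    trajectories: np.ndarray | None = None  # (n_clusters, n_timepoints) override
    library_log_sd: float = 0.1  # lognormal spread of true size factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_expression_counts(
    ann: GenomeAnnotation | None, cfg: ExpressionSimConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a two-condition timecourse count matrix with known truth.

    Gene ids are taken from ``ann`` when it has enough genes, otherwise
    generated. Returns the count matrix and a truth table with each
    gene's cluster label (``"non-DE"`` for null genes) and baseline.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(cfg.timepoints, dtype=float)
    if ann is not None and len(ann.genes) >= cfg.n_genes:
        gene_ids = list(ann.genes["id"].iloc[: cfg.n_genes])
    else:
        gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    clusters = np.full(cfg.n_genes, "non-DE", dtype=object)
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    clusters[de_idx] = [f"{1 + i % cfg.n_clusters}" for i in range(n_de)]

    traj = (
        np.asarray(cfg.trajectories, dtype=float)
        if cfg.trajectories is not None
        else _default_trajectories(times, cfg.n_clusters, cfg.effect_size)
    )
    if traj.shape != (cfg.n_clusters, len(times)):
        raise ValueError("trajectories must be (n_clusters, n_timepoints)")

    baselines = cfg.baseline_mean * rng.lognormal(0.0, cfg.baseline_log_sd, cfg.n_genes)

    sample_rows = []
    for cond in cfg.conditions:
        for tp in times:
            for rep in range(1, cfg.n_replicates + 1):
                sample_rows.append(
                    {
                        "sample": f"{cond}_t{int(tp):02d}_r{rep}",
                        "strain": cond,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample")
    true_sf = rng.lognormal(0.0, cfg.library_log_sd, len(samples))

    effect = np.zeros((cfg.n_genes, len(samples)))
    treat = cfg.conditions[1]
    tp_index = {t: k for k, t in enumerate(times)}
    for j, (_, s) in enumerate(samples.iterrows()):
        if s["strain"] != treat:
            continue
        k = tp_index[s["timepoint"]]
        for g in range(cfg.n_genes):
            lab = clusters[g]
            if lab != "non-DE":
                effect[g, j] = traj[int(lab) - 1, k]

    mu = baselines[:, None] * true_sf[None, :] * np.power(2.0, effect)
    counts = _nb_draw(rng, mu, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples.index)

    truth = pd.DataFrame(
        {"gene": gene_ids, "cluster": clusters, "baseline": baselines, }
    ).set_index("gene")
    truth.attrs["trajectories"] = traj
    truth.attrs["true_size_factors"] = true_sf
    return CountMatrix(counts=counts_df, samples=samples), truth
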