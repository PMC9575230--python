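"""Chromatin-mutant fold-change compendium simulator.

Emulates a single-timepoint expression compendium of deletion mutants:
"similar" mutants share the per-cluster mean log2 fold-change pattern of
the reference experiment, null mutants draw every gene from one global
mean. Gene-level residuals are Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CompendiumSimConfig", "simulate_compendium"]


@dataclass
class CompendiumSimConfig:
    n_mutants: int = 20
    n_similar: int = 3
    # per-cluster mean log2 fold-changes shared by similar mutants;
    # magnitudes are >= 3 residual SDs so the screen's effect-size
    # threshold is meaningful at these conditions
    cluster_means: dict[str, float] = field(
        default_factory=lambda: {
            "1": 2.0, "2": -2.0, "3": 1.5, "4": -1.5, "5": 2.5, "6": -2.5
        }
    )
    null_mean: float = 0.0
    residual_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_similar > self.n_mutants:
            raise ValueError("n_similar cannot exceed n_mutants")


def simulate_compendium(
    cfg: CompendiumSimConfig, clusters: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Mutant fold-change table plus true similar/null labels.

    Parameters
    ----------
    cfg
        Simulation parameters.
    clusters
        Gene -> cluster label; genes labelled ``"non-DE"`` (or any label
        absent from ``cfg.cluster_means``) get the null mean in every
        mutant.

    Returns
    -------
    table
        genes x mutants log2 fold-changes.
    labels
        mutant -> True (similar) / False (null), name-indexed.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = clusters.index
    base = np.full(len(genes), cfg.null_mean)
    for lab, m in cfg.cluster_means.items():
        base[(clusters == lab).to_numpy()] = m

    mutants = [f"mut{i:03d}" for i in range(cfg.n_mutants)]
    similar = np.zeros(cfg.n_mutants, dtype=bool)
    if cfg.n_similar:
        similar[rng.choice(cfg.n_mutants, size=cfg.n_similar, replace=False)] = True

    data = np.empty((len(genes), cfg.n_mutants))
    for j in range(cfg.n_mutants):
        mean = base if similar[j] else np.full(len(genes), cfg.null_mean)
        data[:, j] = mean + rng.normal(0.0, cfg.residual_sd, size=len(genes))

    table = pd.DataFrame(data, index=genes, columns=mutants)
    labels = pd.Series(similar, index=mutants, name="similar")
    return table, labels
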