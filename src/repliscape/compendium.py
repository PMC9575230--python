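"""Chromatin-mutant similarity screen (Kruskal-Wallis + eta-squared).

Each mutant's per-gene fold-changes are grouped by the reference
experiment's expression clusters (plus a non-DE control group) and
tested with a tie-corrected Kruskal-Wallis; the rank-based effect size
is ``eta2 = (H - k + 1) / (n - k)``, clamped to [0, 1]. A mutant is
called similar when its Bonferroni-adjusted p is below 0.001 and eta2
is at least 0.14.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["kruskal_wallis_eta2", "screen_compendium", "KWScreenResult"]

DEFAULT_ALPHA = 0.001
DEFAULT_ETA2 = 0.14


def kruskal_wallis_eta2(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Tie-corrected Kruskal-Wallis H, chi-squared p, and eta-squared.

    ``H = 12 / (n(n+1)) * sum_g R_g^2 / n_g - 3(n+1)``, divided by the
    tie-correction factor; when every value is identical H is defined
    as 0. ``eta2 = (H - k + 1) / (n - k)`` clamped below at 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 values")
    n = len(values)
    ranks = stats.rankdata(values)
    H = 0.0
    for lab in labels:
        r = ranks[groups == lab]
        H += r.sum() ** 2 / len(r)
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    denom = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    H = 0.0 if denom == 0 else H / denom
    p = float(stats.chi2.sf(H, k - 1))
    eta2 = float(np.clip((H - k + 1) / (n - k), 0.0, 1.0))
    return float(H), p, eta2


@dataclass
class KWScreenResult:
    """Per-mutant screen statistics and similar-mutant calls."""

    table: pd.DataFrame  # mutant -> H, pvalue, p_bonf, eta2, similar, sign_agreement
    alpha: float
    eta2_threshold: float

    @property
    def similar_mutants(self) -> list[str]:
        return list(self.table.index[self.table["similar"]])


def screen_compendium(
    compendium: pd.DataFrame,
    groups: pd.Series,
    *,
    reference: pd.Series | None = None,
    control_label: str = "non-DE",
    n_control: int = 300,
    alpha: float = DEFAULT_ALPHA,
    eta2_threshold: float = DEFAULT_ETA2,
    seed: int = 0,
) -> KWScreenResult:
    """Kruskal-Wallis screen of every mutant against the cluster grouping.

    Parameters
    ----------
    compendium
        genes x mutants log2 fold-change table.
    groups
        gene -> cluster label; genes labelled ``control_label`` form the
        control pool, from which ``n_control`` genes are sampled with
        the given seed (all are used when fewer are available).
    reference
        Optional gene -> time-averaged fold-change of the reference
        experiment; when given, per-cluster median sign agreement with
        the mutant is reported (directionality check).

    Bonferroni correction uses the number of mutants tested.
    """
    genes = compendium.index.intersection(groups.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between compendium and grouping")
    groups = groups.loc[genes]
    rng = np.random.default_rng(seed)
    is_ctrl = groups == control_label
    ctrl_genes = list(groups.index[is_ctrl])
    if len(ctrl_genes) > n_control:
        ctrl_genes = list(rng.choice(ctrl_genes, size=n_control, replace=False))
    keep = list(groups.index[~is_ctrl]) + ctrl_genes
    groups = groups.loc[keep]
    sub = compendium.loc[keep]

    cluster_labels = [g for g in groups.unique() if g != control_label]
    ref_sign = None
    if reference is not None:
        ref_sign = {
            c: np.sign(np.median(reference.reindex(groups.index[groups == c]).dropna()))
            for c in cluster_labels
        }

    m = compendium.shape[1]
    rows = []
    garr = groups.to_numpy()
    for mut in compendium.columns:
        vals = sub[mut].to_numpy(dtype=float)
        H, p, eta2 = kruskal_wallis_eta2(vals, garr)
        p_bonf = min(1.0, m * p)
        row = {"mutant": mut, "H": H, "pvalue": p, "p_bonf": p_bonf, "eta2": eta2,
               "similar": (p_bonf < alpha) and (eta2 >= eta2_threshold)}
        if ref_sign is not None:
            agree = [
                np.sign(np.median(vals[garr == c])) == ref_sign[c]
                for c in cluster_labels
            ]
            row["sign_agreement"] = float(np.mean(agree)) if agree else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("mutant")
    return KWScreenResult(table=table, alpha=alpha, eta2_threshold=eta2_threshold)
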