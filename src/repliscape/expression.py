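"""Timecourse differential expression, clustering and group statistics.

The statistical core is re-implemented rather than wrapped: size factors
by the median-of-ratios method, per-timepoint negative-binomial Wald
tests, a timecourse likelihood-ratio test contrasting strain-specific
versus shared per-timepoint means at post-G1 timepoints, seeded k-means
on row z-scored profiles, exact binomial enrichment, time-averaged
fold-changes and Holm-corrected rank-sum group comparisons.

Dispersion is a per-gene method-of-moments estimate pooled across all
replicate groups (floored at 1e-8); no empirical-Bayes shrinkage is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ClusterAssignment",
    "estimate_size_factors",
    "estimate_dispersions",
    "test_per_timepoint",
    "test_timecourse",
    "cluster_profiles",
    "cluster_enrichment",
    "average_fold_change",
    "group_comparison",
]

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``samples`` is indexed by sample name with columns
    ``strain, timepoint, replicate`` covering every counts column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for {sorted(missing)}")

    def drop_genes(self, genes) -> "CountMatrix":
        keep = ~self.counts.index.isin(list(genes))
        return CountMatrix(counts=self.counts.loc[keep], samples=self.samples)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample *j*, the factor is the median over genes expressed
    in every sample of ``count_gj / geometric_mean_g``.
    """
    x = counts.to_numpy(dtype=float)
    expressed = (x > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in all samples")
    logx = np.log(x[expressed])
    log_geo = logx.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logx - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersions(
    cm: CountMatrix, size_factors: pd.Series | None = None
) -> pd.Series:
    """Per-gene NB dispersion by method of moments, pooled over groups.

    Within every (strain, timepoint) replicate group the moment relation
    ``var = mean/sf_bar + alpha * mean^2`` on normalized counts yields a
    dispersion estimate; these are averaged across groups and floored.
    """
    sf = estimate_size_factors(cm.counts) if size_factors is None else size_factors
    norm = cm.counts.to_numpy(float) / sf.reindex(cm.counts.columns).to_numpy()
    groups = cm.samples.groupby(["strain", "timepoint"], sort=False).groups
    est = []
    col_pos = {c: i for i, c in enumerate(cm.counts.columns)}
    for _, members in groups.items():
        cols = [col_pos[m] for m in members if m in col_pos]
        if len(cols) < 2:
            continue
        y = norm[:, cols]
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        inv_sf = np.mean(1.0 / sf.iloc[cols].to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * inv_sf) / m**2
        est.append(np.where(m > 0, a, np.nan))
    if not est:
        raise ValueError("dispersion estimation needs at least one replicated group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alpha = np.nanmean(np.vstack(est), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return pd.Series(
        np.maximum(alpha, DISPERSION_FLOOR), index=cm.counts.index, name="dispersion"
    )


def _group_mean_var(norm, cols, sf_vals, alpha):
    """Mean of normalized counts over a replicate group and the delta-method
    variance of that mean under the NB model."""
    y = norm[:, cols]
    m = y.mean(axis=1)
    var = np.zeros_like(m)
    for c in cols:
        var += m / sf_vals[c] + alpha * m**2
    var /= len(cols) ** 2
    return m, var


def test_per_timepoint(
    cm: CountMatrix,
    timepoint: float,
    *,
    control: str = "control",
    treatment: str = "treatment",
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    excluded_genes=(),
    fdr: float = 0.01,
) -> pd.DataFrame:
    """NB Wald test of treatment vs control at one timepoint.

    Returns per-gene ``log2fc`` (treatment/control on normalized means),
    ``se``, ``stat``, ``pvalue``, ``padj`` (Benjamini-Hochberg) and a
    ``de`` flag at the given FDR. Genes in ``excluded_genes`` are
    removed before testing.
    """
    cm = cm.drop_genes(excluded_genes)
    sf = estimate_size_factors(cm.counts) if size_factors is None else size_factors
    sf = sf.reindex(cm.counts.columns)
    alpha = (
        estimate_dispersions(cm, sf) if dispersions is None else dispersions
    ).reindex(cm.counts.index).to_numpy()

    meta = cm.samples.loc[cm.counts.columns]
    at_t = meta["timepoint"] == timepoint
    cols_c = np.flatnonzero(at_t & (meta["strain"] == control))
    cols_t = np.flatnonzero(at_t & (meta["strain"] == treatment))
    if len(cols_c) == 0 or len(cols_t) == 0:
        raise ValueError(f"timepoint {timepoint} absent for one of the strains")

    sf_vals = sf.to_numpy()
    norm = cm.counts.to_numpy(float) / sf_vals
    m_c, v_c = _group_mean_var(norm, cols_c, sf_vals, alpha)
    m_t, v_t = _group_mean_var(norm, cols_t, sf_vals, alpha)

    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m_t / m_c)
        # delta method on log2 of each group mean
        var_l2 = v_c / np.maximum(m_c, eps) ** 2 + v_t / np.maximum(m_t, eps) ** 2
        se = np.sqrt(var_l2) / np.log(2.0)
        stat = log2fc / se
    both_zero = (m_c == 0) & (m_t == 0)
    stat = np.where(both_zero, 0.0, stat)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": np.where(both_zero, 0.0, log2fc),
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "de": padj < fdr,
        },
        index=cm.counts.index,
    )


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB(mu, alpha) log-pmf; Poisson limit for tiny alpha."""
    mu = np.maximum(mu, 1e-10)
    ll = np.empty(k.shape)
    tiny = alpha < 1e-6
    if tiny.any():
        ll[tiny] = stats.poisson.logpmf(k[tiny], mu[tiny])
    if (~tiny).any():
        a = alpha[~tiny]
        r = 1.0 / a
        p = r / (r + mu[~tiny])
        ll[~tiny] = stats.nbinom.logpmf(k[~tiny], r, p)
    return ll.sum(axis=1)


def test_timecourse(
    cm: CountMatrix,
    *,
    control: str = "control",
    treatment: str = "treatment",
    g1_timepoint: float = 0.0,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    excluded_genes=(),
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Likelihood-ratio test for a strain difference at any post-G1 time.

    Full model: one normalized mean per (strain, timepoint) for post-G1
    timepoints and a shared mean at G1. Reduced model: one mean per
    timepoint. The statistic is chi-squared with df equal to the number
    of post-G1 timepoints.
    """
    cm = cm.drop_genes(excluded_genes)
    sf = estimate_size_factors(cm.counts) if size_factors is None else size_factors
    sf = sf.reindex(cm.counts.columns)
    alpha = (
        estimate_dispersions(cm, sf) if dispersions is None else dispersions
    ).reindex(cm.counts.index).to_numpy()

    meta = cm.samples.loc[cm.counts.columns]
    timepoints = sorted(meta["timepoint"].unique())
    post = [t for t in timepoints if t != g1_timepoint]
    if len(post) < 2:
        raise ValueError("need at least 2 post-G1 timepoints")

    sf_vals = sf.to_numpy()
    k = cm.counts.to_numpy(float)
    norm = k / sf_vals

    def model_mu(group_of_sample: list) -> np.ndarray:
        """Fit group means (mean of normalized counts) and expand to mu."""
        labels = pd.Series(group_of_sample, index=cm.counts.columns)
        mu = np.empty_like(norm)
        for g in labels.unique():
            cols = np.flatnonzero((labels == g).to_numpy())
            m = norm[:, cols].mean(axis=1)
            mu[:, cols] = m[:, None] * sf_vals[cols][None, :]
        return mu

    full_groups = [
        "G1" if meta.loc[s, "timepoint"] == g1_timepoint
        else f"{meta.loc[s, 'strain']}@{meta.loc[s, 'timepoint']}"
        for s in cm.counts.columns
    ]
    red_groups = [f"t@{meta.loc[s, 'timepoint']}" for s in cm.counts.columns]

    a2 = alpha[:, None] * np.ones_like(k)
    ll_full = _nb_loglik(k, model_mu(full_groups), a2)
    ll_red = _nb_loglik(k, model_mu(red_groups), a2)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    df = len(post)
    pvalue = stats.chi2.sf(lrt, df)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return pd.DataFrame(
        {"stat": lrt, "df": df, "pvalue": pvalue, "padj": padj, "de": padj < fdr},
        index=cm.counts.index,
    )


@dataclass
class ClusterAssignment:
    """k-means labels (1..k) over DE genes plus cluster mean profiles."""

    labels: pd.Series  # gene -> cluster id (int)
    centers: pd.DataFrame  # cluster id -> mean z-scored profile
    dropped: list[str] = field(default_factory=list)

    def as_series(self, all_genes=None) -> pd.Series:
        """Labels as strings, with non-clustered genes marked 'non-DE'."""
        lab = self.labels.astype(str)
        if all_genes is None:
            return lab
        return lab.reindex(all_genes).fillna("non-DE")


def zscore_rows(mat: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scoring; rows with zero SD are dropped (returned separately)."""
    x = mat.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    z = (x - mu) / np.where(sd == 0, 1.0, sd)
    dropped = list(mat.index[flat])
    return pd.DataFrame(z[~flat], index=mat.index[~flat], columns=mat.columns), dropped


def cluster_profiles(
    mat: pd.DataFrame, k: int = 6, max_iter: int = 50, seed: int = 0
) -> ClusterAssignment:
    """Seeded k-means++ on row z-scored expression profiles."""
    z, dropped = zscore_rows(mat)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant-expression genes", stacklevel=2)
    if len(z) < k:
        raise ValueError(f"need at least k={k} genes with non-constant profiles")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    max_iter=max_iter, random_state=seed).fit(z.to_numpy())
    labels = pd.Series(km.labels_ + 1, index=z.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, index=range(1, k + 1), columns=mat.columns)
    return ClusterAssignment(labels=labels, centers=centers, dropped=dropped)


def cluster_enrichment(
    cluster_genes, annotated_genes, genome_size: int
) -> tuple[str, float]:
    """Exact binomial over/under-representation test.

    With *n* cluster genes of which *K* carry the annotation, and *M* of
    *G* genes annotated genome-wide, the over-tail is ``P(X >= K)`` and
    the under-tail ``P(X <= K)`` for ``X ~ Binomial(n, M/G)``; the
    smaller tail and its direction are reported.
    """
    cluster = set(cluster_genes)
    annotated = set(annotated_genes)
    n, M = len(cluster), len(annotated)
    if n > genome_size or M > genome_size:
        raise ValueError("set sizes cannot exceed genome size")
    K = len(cluster & annotated)
    p0 = M / genome_size
    p_over = float(stats.binom.sf(K - 1, n, p0))
    p_under = float(stats.binom.cdf(K, n, p0))
    if p_over <= p_under:
        return "over", p_over
    return "under", p_under


def average_fold_change(
    log2fc: pd.DataFrame, *, g1_timepoint: float = 0.0
) -> pd.Series:
    """Time-averaged log2 fold-change over post-G1 timepoints.

    ``log2fc`` has one column per timepoint (numeric labels); the G1
    column, if present, is excluded from the average.
    """
    cols = [c for c in log2fc.columns if float(c) != g1_timepoint]
    if not cols:
        raise ValueError("no post-G1 timepoints in fold-change table")
    return log2fc[cols].mean(axis=1).rename("avg_log2fc")


def group_comparison(
    values: pd.Series,
    groups: dict[str, list],
    non_de_genes,
    *,
    n_control: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Each group versus a seeded random non-DE control by rank-sum test.

    Two-sided Wilcoxon rank-sum (normal approximation with tie handling
    and continuity correction) of each group against ``n_control`` genes
    sampled without replacement from ``non_de_genes``; Holm step-down
    across groups. The control row is included with p = NaN.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in non_de_genes if g in values.index]
    if len(pool) < n_control:
        raise ValueError("non-DE pool smaller than requested control size")
    control = list(rng.choice(pool, size=n_control, replace=False))
    ctrl_vals = values.loc[control].to_numpy()

    rows = []
    pvals = []
    for name, genes in groups.items():
        gv = values.loc[[g for g in genes if g in values.index]].to_numpy()
        if len(gv) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        res = stats.mannwhitneyu(
            gv, ctrl_vals, alternative="two-sided", use_continuity=True,
            method="asymptotic",
        )
        rows.append({"group": name, "n": len(gv), "median": float(np.median(gv)),
                     "pvalue": float(res.pvalue)})
        pvals.append(res.pvalue)
    padj = multipletests(pvals, method="holm")[1]
    for r, p in zip(rows, padj):
        r["p_holm"] = float(p)
    rows.append({"group": "control", "n": n_control,
                 "median": float(np.median(ctrl_vals)),
                 "pvalue": np.nan, "p_holm": np.nan})
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["control_genes"] = control
    return out
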