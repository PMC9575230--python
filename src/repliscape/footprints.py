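"""Sub-nucleosomal TF-footprint pipeline.

Fragments shorter than 100 bp are selected, size-matched down-sampled
across timepoints (per fragment length, to the timepoint with the
fewest), pooled to call candidate peaks, and filtered: a peak is high
confidence when the sum over samples of log2(normalized count +
pseudocount) exceeds 75, and differential when it sits in the 1-kb
strand-aware promoter of a gene and shows at least a 2-fold
strain difference (|log2 ratio| >= 1) at some post-G1 timepoint. Peaks
are annotated to the nearest TF site within 200 bp and summarized per
TF as the two ratios of a binding-change versus expression-effect
scatter. Normalization is counts per million per sample with
pseudocount 1 (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "select_subnucleosomal",
    "size_matched_downsample",
    "fragment_coverage",
    "call_peaks_merged",
    "peak_sample_counts",
    "filter_high_confidence",
    "differential_peaks",
    "annotate_to_tf_sites",
    "tf_effect_ratios",
    "TFSummary",
]

SUBNUC_MAX_LENGTH = 100  # strict upper bound, exclusive
CONFIDENCE_THRESHOLD = 75.0
PROMOTER_BP = 1000
SITE_MAX_DIST = 200


def select_subnucleosomal(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep fragments strictly shorter than 100 bp."""
    if not len(fragments):
        return fragments.copy()
    length = fragments["end"] - fragments["start"]
    return fragments[length < SUBNUC_MAX_LENGTH].reset_index(drop=True)


def size_matched_downsample(
    sets: dict, seed: int = 0
) -> dict:
    """Equalize per-length fragment counts across samples.

    For every fragment length, each sample retains a seeded uniform
    sample (without replacement) of exactly the minimum count of that
    length over samples; after this the per-length histograms are
    identical across samples.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 samples to size-match")
    rng = np.random.default_rng(seed)
    lengths = {k: (df["end"] - df["start"]).to_numpy() for k, df in sets.items()}
    all_lengths = sorted(set(np.concatenate([v for v in lengths.values() if len(v)]))
                         ) if any(len(v) for v in lengths.values()) else []
    out = {}
    keep_masks = {k: np.zeros(len(df), dtype=bool) for k, df in sets.items()}
    for ell in all_lengths:
        n_min = min(int((lengths[k] == ell).sum()) for k in sets)
        if n_min == 0:
            continue
        for k in sets:
            idx = np.flatnonzero(lengths[k] == ell)
            chosen = rng.choice(idx, size=n_min, replace=False) if len(idx) > n_min else idx
            keep_masks[k][chosen] = True
    for k, df in sets.items():
        out[k] = df[keep_masks[k]].reset_index(drop=True)
    return out


def fragment_coverage(
    fragments: pd.DataFrame, chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-bp coverage of fragment intervals (0-based half-open)."""
    cov = {c: np.zeros(L, dtype=float) for c, L in chrom_lengths.items()}
    for chrom, grp in fragments.groupby("chrom"):
        d = np.zeros(chrom_lengths[chrom] + 1)
        np.add.at(d, grp["start"].to_numpy(), 1.0)
        np.add.at(d, grp["end"].to_numpy(), -1.0)
        cov[chrom] = np.cumsum(d[:-1])
    return cov


def call_peaks_merged(
    coverage: dict[str, np.ndarray],
    *,
    min_coverage: float = 2.0,
    merge_gap: int = 30,
) -> pd.DataFrame:
    """Maximal runs of coverage >= min_coverage, close runs merged.

    Runs separated by less than ``merge_gap`` bp are merged; output is
    sorted and non-overlapping.
    """
    rows = []
    for chrom, cov in coverage.items():
        above = cov >= min_coverage
        if not above.any():
            continue
        d = np.diff(above.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(cov))
        merged = [[starts[0], ends[0]]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def peak_sample_counts(
    peaks: pd.DataFrame, sets: dict, *, normalize: bool = True
) -> pd.DataFrame:
    """Peak x sample fragment-center counts, optionally per-million.

    A fragment is assigned to a peak when its midpoint lies within the
    peak interval. Normalization is counts-per-million of the sample's
    total fragment count.
    """
    data = {}
    for key, df in sets.items():
        col = np.zeros(len(peaks))
        total = len(df)
        if total:
            centers = ((df["start"] + df["end"]) // 2).to_numpy()
            chroms = df["chrom"].to_numpy()
            for i, p in peaks.iterrows():
                on = chroms == p["chrom"]
                col[i] = np.count_nonzero(
                    (centers[on] >= p["start"]) & (centers[on] < p["end"])
                )
        if normalize and total:
            col = col / total * 1e6
        data[key] = col
    return pd.DataFrame(data, index=peaks.index)


def filter_high_confidence(
    norm_counts: pd.DataFrame,
    *,
    pseudocount: float = 1.0,
    threshold: float = CONFIDENCE_THRESHOLD,
) -> pd.DataFrame:
    """Flag peaks whose summed log2 normalized counts exceed the threshold.

    ``sum_log2 = sum over samples of log2(count + pseudocount)``; the
    flag requires strict inequality (> threshold).
    """
    x = norm_counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("normalized counts must be non-negative")
    sum_log2 = np.log2(x + pseudocount).sum(axis=1)
    return pd.DataFrame(
        {"sum_log2": sum_log2, "high_confidence": sum_log2 > threshold},
        index=norm_counts.index,
    )


def assign_promoter_gene(
    peaks: pd.DataFrame, genes: pd.DataFrame, *, promoter_bp: int = PROMOTER_BP
) -> pd.Series:
    """Gene whose 1-kb strand-aware promoter contains the peak midpoint.

    The promoter is the ``promoter_bp`` strictly upstream of the TSS:
    [TSS-promoter_bp, TSS) for + strand, (TSS, TSS+promoter_bp] for -.
    When several promoters contain the midpoint the nearest TSS wins.
    """
    out = pd.Series(index=peaks.index, dtype=object)
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    for i, p in peaks.iterrows():
        mid = centers[peaks.index.get_loc(i)]
        best = None
        for _, g in genes[genes["chrom"] == p["chrom"]].iterrows():
            if g["strand"] == "+":
                inside = g["tss"] - promoter_bp <= mid < g["tss"]
            else:
                inside = g["tss"] < mid <= g["tss"] + promoter_bp
            if inside:
                d = abs(mid - g["tss"])
                if best is None or d < best[0]:
                    best = (d, g["id"])
        out.loc[i] = best[1] if best else None
    return out


def differential_peaks(
    peaks: pd.DataFrame,
    norm_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    control: str = "control",
    treatment: str = "early",
    g1_timepoint: float = 0.0,
    pseudocount: float = 1.0,
    min_abs_log2: float = 1.0,
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Per-timepoint strain log2 ratios and the differential flag.

    A peak is differential iff its midpoint lies in a gene's 1-kb
    upstream promoter and |log2(treatment/control)| >= ``min_abs_log2``
    at at least one post-G1 timepoint. ``sample_meta`` maps the columns
    of ``norm_counts`` to (strain, timepoint); replicate columns of the
    same (strain, timepoint) are averaged before the ratio.
    """
    meta = sample_meta.loc[list(norm_counts.columns)]
    timepoints = sorted(meta["timepoint"].unique())
    ratios = {}
    for t in timepoints:
        c_cols = meta[(meta["strain"] == control) & (meta["timepoint"] == t)].index
        t_cols = meta[(meta["strain"] == treatment) & (meta["timepoint"] == t)].index
        if len(c_cols) == 0 or len(t_cols) == 0:
            raise ValueError(f"timepoint {t} missing in one strain")
        mc = norm_counts[list(c_cols)].mean(axis=1)
        mt = norm_counts[list(t_cols)].mean(axis=1)
        ratios[t] = np.log2((mt + pseudocount) / (mc + pseudocount))
    ratio_df = pd.DataFrame(ratios, index=norm_counts.index)
    post = [t for t in timepoints if t != g1_timepoint]
    max_abs = ratio_df[post].abs().max(axis=1)

    promoter_gene = assign_promoter_gene(peaks, genes, promoter_bp=promoter_bp)
    out = peaks.copy()
    out["promoter_gene"] = promoter_gene
    out["max_abs_log2_post_g1"] = max_abs
    out["differential"] = promoter_gene.notna() & (max_abs >= min_abs_log2)
    for t in timepoints:
        out[f"log2_ratio_t{t:g}"] = ratio_df[t]
    return out


def annotate_to_tf_sites(
    peaks: pd.DataFrame, tf_sites: pd.DataFrame, *, max_dist: int = SITE_MAX_DIST
) -> pd.DataFrame:
    """Label peaks with the nearest TF site within ``max_dist`` bp.

    Distance is peak midpoint to site position, inclusive at the bound;
    ties go to the smaller distance then the lexically smaller TF name.
    Unlabeled peaks carry ``tf = None``.
    """
    out = peaks.copy()
    tfs = []
    for _, p in peaks.iterrows():
        mid = (p["start"] + p["end"]) // 2
        on = tf_sites[tf_sites["chrom"] == p["chrom"]]
        best = None
        for _, s in on.iterrows():
            d = abs(int(s["pos"]) - mid)
            if d <= max_dist and (best is None or (d, s["tf"]) < best):
                best = (d, s["tf"])
        tfs.append(best[1] if best else None)
    out["tf"] = tfs
    return out


@dataclass
class TFSummary:
    """Per-TF binding-change and expression-effect ratios (plus baseline)."""

    per_tf: pd.DataFrame  # tf -> total, changed, x_ratio, y_ratio
    baseline_x: float
    baseline_y: float


def tf_effect_ratios(peaks: pd.DataFrame, de_genes) -> TFSummary:
    """The two-ratio TF scatter: binding change vs expression effect.

    For each TF: ``x = differential peaks / total peaks`` and
    ``y = differential peaks in DE-gene promoters / differential
    peaks`` (NaN when no peak is differential). TFs with zero peaks are
    omitted. The baseline ratios over all input peaks (annotated or
    not) are reported alongside.
    """
    de = set(de_genes)
    in_de = peaks["promoter_gene"].isin(de)
    n_diff_all = int(peaks["differential"].sum())
    baseline_x = n_diff_all / len(peaks) if len(peaks) else np.nan
    baseline_y = (
        float((peaks["differential"] & in_de).sum() / n_diff_all)
        if n_diff_all else np.nan
    )
    rows = []
    annotated = peaks[peaks["tf"].notna()]
    for tf, grp in annotated.groupby("tf"):
        total = len(grp)
        changed = int(grp["differential"].sum())
        y = float((grp["differential"] & grp["promoter_gene"].isin(de)).sum() / changed
                  ) if changed else np.nan
        rows.append({"tf": tf, "total": total, "changed": changed,
                     "x_ratio": changed / total, "y_ratio": y})
    per_tf = pd.DataFrame(rows, columns=["tf", "total", "changed", "x_ratio", "y_ratio"])
    if len(per_tf):
        per_tf = per_tf.set_index("tf")
    return TFSummary(per_tf=per_tf, baseline_x=baseline_x, baseline_y=baseline_y)
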