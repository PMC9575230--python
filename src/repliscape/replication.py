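"""Replication-timing (Trep) profiling from copy-number timecourses.

The pipeline: per-bin read counts at each timepoint are divided by the
G1 sample and rescaled so the genome-wide mean ratio equals the bulk
replicated fraction (a value between 1 and 2); a bounded four-parameter
logistic is fitted to each bin's ratio trajectory; Trep is the time at
which the fitted curve crosses ratio 1.5 (half-maximal replication).
Profiles are smoothed with a mask-aware moving average, and local
minima/maxima of the smoothed profile are called as origins /
termination zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .annotation import GenomeAnnotation

__all__ = [
    "BinCopyNumber",
    "TrepFit",
    "TrepProfile",
    "OriginCall",
    "compute_copy_number",
    "fit_trep",
    "fit_trep_profile",
    "smooth_profile",
    "call_origins_terminations",
    "quintile_summary",
    "region_trep",
]


@dataclass
class BinCopyNumber:
    """Normalized per-bin copy-number ratios across a timecourse."""

    bins: pd.DataFrame  # chrom, start, end
    timepoints: np.ndarray
    ratio: np.ndarray  # (n_bins, n_timepoints); NaN where G1 coverage was 0
    bulk: np.ndarray  # (n_timepoints,)


def compute_copy_number(
    counts: np.ndarray,
    g1_counts: np.ndarray,
    bulk: np.ndarray,
    *,
    bins: pd.DataFrame | None = None,
    timepoints: np.ndarray | None = None,
) -> BinCopyNumber:
    """Ratio-to-G1 copy number, bulk-normalized per timepoint.

    The raw ratio ``counts / g1`` is rescaled at each timepoint by a
    single multiplicative constant so that its genome-wide mean equals
    the bulk replicated-fraction value for that timepoint. Bins with
    zero G1 coverage are masked (NaN), not imputed.
    """
    counts = np.asarray(counts, dtype=float)
    g1 = np.asarray(g1_counts, dtype=float)
    bulk = np.asarray(bulk, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != g1.shape[0]:
        raise ValueError("counts must be (n_bins, n_timepoints) matching g1_counts")
    if counts.shape[1] != len(bulk):
        raise ValueError("bulk must have one value per timepoint")
    if np.any((bulk < 1.0) | (bulk > 2.0)):
        raise ValueError("bulk values must lie in [1, 2]")
    if not np.any(g1 > 0):
        raise ValueError("all G1 counts are zero")

    mask = g1 > 0
    ratio = np.full_like(counts, np.nan)
    ratio[mask] = counts[mask] / g1[mask, None]
    means = np.nanmean(ratio, axis=0)
    with np.errstate(invalid="ignore"):
        ratio *= (bulk / means)[None, :]

    if bins is None:
        bins = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(g1)), "end": np.arange(len(g1)) + 1}
        )
    if timepoints is None:
        timepoints = np.arange(counts.shape[1], dtype=float)
    return BinCopyNumber(bins=bins, timepoints=np.asarray(timepoints, float),
                         ratio=ratio, bulk=bulk)


@dataclass
class TrepFit:
    """Four-parameter logistic fit of one bin's ratio trajectory."""

    trep: float  # minutes; NaN when fit_ok is False
    floor: float
    ceiling: float
    midpoint: float
    slope: float
    fit_ok: bool

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return _logistic(t, self.floor, self.ceiling, self.slope, self.midpoint)


@dataclass
class TrepProfile:
    """Per-bin Trep estimates for one condition."""

    bins: pd.DataFrame
    trep: np.ndarray  # NaN where fit failed
    fit_ok: np.ndarray
    fit_params: np.ndarray  # (n_bins, 4): floor, ceiling, midpoint, slope
    smoothed: np.ndarray | None = None


def _logistic(t, L, U, k, m):
    return L + (U - L) / (1.0 + np.exp(-k * (t - m)))


def fit_trep(
    timepoints: np.ndarray,
    ratios: np.ndarray,
    *,
    floor_bounds: tuple[float, float] = (0.8, 1.2),
    ceiling_bounds: tuple[float, float] = (1.8, 2.2),
    max_slope: float = 10.0,
    min_final_ratio: float = 1.4,
    max_rms: float = 0.25,
    n_starts: int = 3,
) -> TrepFit:
    """Fit a bounded sigmoid to one bin's ratio trajectory.

    Trep is the exact solution of ``fitted(t) = 1.5``, so evaluating the
    fitted curve at the returned Trep always gives ratio 1.5. The fit is
    flagged not-OK (Trep = NaN) when the trajectory never reaches
    ``min_final_ratio``, when the residual RMS exceeds ``max_rms``, when
    1.5 is outside the fitted (floor, ceiling) range, or when the
    crossing time falls outside the sampled timecourse.
    """
    t = np.asarray(timepoints, dtype=float)
    r = np.asarray(ratios, dtype=float)
    keep = np.isfinite(r)
    t, r = t[keep], r[keep]
    failed = TrepFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    if len(t) < 4:
        return failed
    if np.max(r[-2:]) < min_final_ratio:
        return failed

    lo = [floor_bounds[0], ceiling_bounds[0], 1e-3, t[0]]
    hi = [floor_bounds[1], ceiling_bounds[1], max_slope, t[-1]]
    # midpoint starts spread over the span to dodge local minima
    m_starts = np.quantile(t, np.linspace(0.25, 0.75, n_starts))
    best = None
    for m0 in m_starts:
        p0 = [1.0, 2.0, 0.3, float(np.clip(m0, t[0], t[-1]))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _logistic, t, r, p0=p0, bounds=(lo, hi), maxfev=2000
                )
        except (RuntimeError, ValueError):
            continue
        rms = float(np.sqrt(np.mean((_logistic(t, *popt) - r) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        return failed
    (L, U, k, m), rms = best
    if rms > max_rms or not (L < 1.5 < U):
        return TrepFit(np.nan, L, U, m, k, False)
    trep = m - np.log((U - 1.5) / (1.5 - L)) / k
    if not (t[0] <= trep <= t[-1]):
        return TrepFit(np.nan, L, U, m, k, False)
    return TrepFit(float(trep), float(L), float(U), float(m), float(k), True)


def fit_trep_profile(cn: BinCopyNumber, **fit_kwargs) -> TrepProfile:
    """Fit every bin of a normalized copy-number matrix."""
    n = cn.ratio.shape[0]
    trep = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    params = np.full((n, 4), np.nan)
    for b in range(n):
        f = fit_trep(cn.timepoints, cn.ratio[b], **fit_kwargs)
        trep[b] = f.trep
        ok[b] = f.fit_ok
        params[b] = (f.floor, f.ceiling, f.midpoint, f.slope)
    return TrepProfile(bins=cn.bins, trep=trep, fit_ok=ok, fit_params=params)


def smooth_profile(
    trep: np.ndarray, window: int, *, chroms: np.ndarray | None = None
) -> np.ndarray:
    """Centered moving average skipping undefined (NaN) bins.

    Chromosome boundaries are never mixed: when ``chroms`` is given the
    average is computed within each chromosome's run of bins.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    trep = np.asarray(trep, dtype=float)
    if chroms is None:
        chroms = np.zeros(len(trep), dtype=int)
    out = np.full_like(trep, np.nan)
    kernel = np.ones(window)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        x = trep[idx]
        if window > len(x):
            raise ValueError("window larger than chromosome")
        vals = np.nan_to_num(x)
        mask = np.isfinite(x).astype(float)
        num = np.convolve(vals * mask, kernel, mode="same")
        den = np.convolve(mask, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[den == 0] = np.nan
        out[idx] = sm
    return out


@dataclass
class OriginCall:
    index: int  # bin index within the profile passed in
    kind: str  # "origin" | "termination"
    trep: float


def call_origins_terminations(
    smoothed: np.ndarray, min_prominence: float = 2.0
) -> list[OriginCall]:
    """Local Trep minima (origins) and maxima (terminations).

    Calls alternate along the profile; within a run of same-kind calls
    only the most extreme is kept. Operates on a single chromosome's
    smoothed profile.
    """
    x = np.asarray(smoothed, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("smoothed profile must be defined on >= 3 bins")
    idx_map = np.flatnonzero(finite)
    y = x[finite]
    mins, _ = find_peaks(-y, prominence=min_prominence)
    maxs, _ = find_peaks(y, prominence=min_prominence)
    calls = [OriginCall(int(idx_map[i]), "origin", float(y[i])) for i in mins]
    calls += [OriginCall(int(idx_map[i]), "termination", float(y[i])) for i in maxs]
    calls.sort(key=lambda c: c.index)

    # enforce alternation: within a same-kind run keep the extreme value
    out: list[OriginCall] = []
    for c in calls:
        if out and out[-1].kind == c.kind:
            if c.kind == "origin":
                if c.trep < out[-1].trep:
                    out[-1] = c
            elif c.trep > out[-1].trep:
                out[-1] = c
        else:
            out.append(c)
    return out


@dataclass
class QuintileSummary:
    quintile: np.ndarray  # per-origin quintile 1..5 (by control-Trep rank)
    control: list[np.ndarray]
    treatment: list[np.ndarray]
    mean_advance: np.ndarray  # per-quintile mean(control - treatment)


def quintile_summary(
    control_trep: np.ndarray,
    treatment_trep: np.ndarray,
    positions: np.ndarray | None = None,
) -> QuintileSummary:
    """Origins binned into quintiles by control-strain Trep rank.

    Ties in control Trep are broken by position order. The advance of a
    quintile is mean(control Trep - treatment Trep), positive when the
    treatment replicates earlier.
    """
    c = np.asarray(control_trep, dtype=float)
    tr = np.asarray(treatment_trep, dtype=float)
    if len(c) != len(tr):
        raise ValueError("control and treatment must have equal length")
    if len(c) < 5:
        raise ValueError("need at least 5 origins for quintiles")
    if positions is None:
        positions = np.arange(len(c))
    order = np.lexsort((np.asarray(positions), c))
    rank = np.empty(len(c), dtype=int)
    rank[order] = np.arange(len(c))
    quint = rank * 5 // len(c) + 1
    ctrl = [c[quint == q] for q in range(1, 6)]
    trt = [tr[quint == q] for q in range(1, 6)]
    adv = np.array([np.mean(a - b) for a, b in zip(ctrl, trt)])
    return QuintileSummary(quintile=quint, control=ctrl, treatment=trt, mean_advance=adv)


def region_trep(
    trep: np.ndarray,
    bins: pd.DataFrame,
    ann: GenomeAnnotation,
    region_kind: str,
    *,
    centromere_margin: int = 10_000,
) -> np.ndarray:
    """Trep values of bins in telomeric or centromeric regions.

    Telomeric bins overlap the zones within ``ann.telomere_margin`` of
    either chromosome end; centromeric bins lie within
    ``centromere_margin`` of the centromere position.
    """
    sel = np.zeros(len(bins), dtype=bool)
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    if region_kind == "telomere":
        for name, L in ann.chromosomes:
            m = ann.telomere_margin
            on = chroms == name
            sel |= on & ((starts < m) | (ends > L - m))
    elif region_kind == "centromere":
        for name, _ in ann.chromosomes:
            cen = ann.centromeres[name]
            on = chroms == name
            sel |= on & (starts < cen + centromere_margin) & (ends > cen - centromere_margin)
    else:
        raise ValueError("region_kind must be 'telomere' or 'centromere'")
    return np.asarray(trep, dtype=float)[sel]
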