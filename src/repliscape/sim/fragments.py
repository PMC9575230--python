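"""MNase fragment simulator: phased nucleosome arrays + TF footprints.

Two fragment classes are generated per (condition, timepoint) sample:

* nucleosomal fragments (lengths 140-180 bp) centred on jittered dyads of
  a regular array downstream of each gene's TSS (+1 at a fixed offset,
  then one dyad per repeat length), and
* sub-nucleosomal fragments (lengths < 100 bp) centred on annotated TF
  sites, with per-sample occupancy controlling their expected number.

Per-sample jitter SD and +1 shift can be scheduled over the timecourse
to emulate the transient S-phase chromatin disorganization of a
global-early-replication strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from ..annotation import GenomeAnnotation

__all__ = ["NucleosomeArraySpec", "FragmentSimConfig", "simulate_mnase_fragments"]

SampleKey = tuple[str, float]  # (condition, timepoint)


@dataclass
class NucleosomeArraySpec:
    """Regular nucleosome array downstream of each TSS."""

    plus_one_offset: int = 60  # bp from TSS to the +1 dyad, into the gene body
    repeat_length: int = 165
    n_nucleosomes: int = 5
    jitter_sd: float = 10.0  # bp
    occupancy: float = 1.0  # in [0, 1]

    def __post_init__(self) -> None:
        if self.repeat_length <= 0:
            raise ValueError("repeat_length must be > 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class FragmentSimConfig:
    """Fragment counts, length classes and per-sample dynamics.

    ``jitter_sd_by_sample`` / ``plus_one_shift_by_sample`` override the
    array's jitter SD or shift every dyad downstream for specific
    samples. ``tf_occupancy`` maps (condition, timepoint) -> occupancy in
    [0, 1], applied to all TF sites unless the site's TF name appears in
    ``tf_occupancy_by_name``.
    """

    conditions: tuple[str, ...] = ("control", "early")
    timepoints: tuple[float, ...] = tuple(range(0, 65, 5))
    array: NucleosomeArraySpec = field(default_factory=NucleosomeArraySpec)
    reads_per_nucleosome: float = 30.0
    reads_per_tf_site: float = 150.0
    nuc_length_range: tuple[int, int] = (140, 180)  # inclusive
    subnuc_length_range: tuple[int, int] = (30, 99)  # inclusive, all < 100
    jitter_sd_by_sample: dict[SampleKey, float] = field(default_factory=dict)
    plus_one_shift_by_sample: dict[SampleKey, float] = field(default_factory=dict)
    tf_occupancy: dict[SampleKey, float] | float = 0.9
    tf_occupancy_by_name: dict[str, dict[SampleKey, float]] = field(default_factory=dict)
    site_jitter_sd: float = 5.0
    seed: int = 0

    def occupancy_for(self, tf: str, key: SampleKey) -> float:
        table = self.tf_occupancy_by_name.get(tf)
        if table is not None and key in table:
            occ = table[key]
        elif isinstance(self.tf_occupancy, dict):
            occ = self.tf_occupancy.get(key, 0.0)
        else:
            occ = self.tf_occupancy
        if not 0.0 <= occ <= 1.0:
            raise ValueError("TF occupancy must be in [0, 1]")
        return occ


def _fragments_around(
    centers: np.ndarray, lengths: np.ndarray, chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Half-open intervals of given lengths centred on the given points."""
    starts = np.round(centers).astype(int) - lengths // 2
    ends = starts + lengths
    keep = (starts >= 0) & (ends <= chrom_len)
    return starts[keep], ends[keep]


def simulate_mnase_fragments(
    ann: GenomeAnnotation, cfg: FragmentSimConfig
) -> dict[SampleKey, pd.DataFrame]:
    """One fragment table (chrom, start, end) per (condition, timepoint).

    Fragment counts per dyad / site are Poisson around
    ``reads_per_nucleosome * occupancy`` and
    ``reads_per_tf_site * occupancy``; lengths are uniform over the
    class's range, so the nucleosomal class is entirely within
    [140, 180] and the sub-nucleosomal class entirely below 100 bp.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_lengths = ann.chrom_lengths
    out: dict[SampleKey, pd.DataFrame] = {}
    arr = cfg.array
    nlo, nhi = cfg.nuc_length_range
    slo, shi = cfg.subnuc_length_range
    if shi >= 100:
        raise ValueError("sub-nucleosomal lengths must be < 100 bp")

    for cond in cfg.conditions:
        for tp in cfg.timepoints:
            key = (cond, float(tp))
            jitter = cfg.jitter_sd_by_sample.get(key, arr.jitter_sd)
            shift = cfg.plus_one_shift_by_sample.get(key, 0.0)
            rows: list[pd.DataFrame] = []
            for _, g in ann.genes.iterrows():
                sign = 1 if g["strand"] == "+" else -1
                dyads = g["tss"] + sign * (
                    arr.plus_one_offset
                    + shift
                    + arr.repeat_length * np.arange(arr.n_nucleosomes)
                )
                for dyad in dyads:
                    n = rng.poisson(cfg.reads_per_nucleosome * arr.occupancy)
                    if n == 0:
                        continue
                    centers = dyad + (rng.normal(0.0, jitter, size=n) if jitter > 0 else 0.0)
                    lengths = rng.integers(nlo, nhi + 1, size=n)
                    s, e = _fragments_around(
                        np.atleast_1d(centers * np.ones(n)), lengths, chrom_lengths[g["chrom"]]
                    )
                    rows.append(pd.DataFrame({"chrom": g["chrom"], "start": s, "end": e}))
            for _, site in ann.tf_sites.iterrows():
                occ = cfg.occupancy_for(site["tf"], key)
                n = rng.poisson(cfg.reads_per_tf_site * occ) if occ > 0 else 0
                if n == 0:
                    continue
                centers = site["pos"] + rng.normal(0.0, cfg.site_jitter_sd, size=n)
                lengths = rng.integers(slo, shi + 1, size=n)
                s, e = _fragments_around(centers, lengths, chrom_lengths[site["chrom"]])
                rows.append(pd.DataFrame({"chrom": site["chrom"], "start": s, "end": e}))
            if rows:
                df = pd.concat(rows, ignore_index=True)
                df = df.sort_values(["chrom", "start", "end"], ignore_index=True)
            else:
                df = pd.DataFrame(columns=["chrom", "start", "end"])
            out[key] = df
    return out
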