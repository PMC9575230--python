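"""Genome annotation container and synthetic-annotation builder.

The annotation is the coordinate backbone shared by every analysis stage:
chromosomes, strand-aware genes with a TSS, replication origins (ARS),
centromeres, telomeric zones and TF motif sites. All coordinates are
0-based; gene intervals are half-open [start, end).

Convention: the TSS of a ``+`` strand gene is ``start`` and of a ``-``
strand gene is ``end``; upstream/downstream arithmetic elsewhere in the
package is relative to this TSS in the direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "AnnotationConfig",
    "InfeasiblePackingError",
    "make_genome_annotation",
]

GENE_COLUMNS = ["id", "chrom", "start", "end", "strand", "tss"]
ORIGIN_COLUMNS = ["id", "chrom", "pos", "licensed"]
TF_COLUMNS = ["tf", "chrom", "pos", "strand"]


class InfeasiblePackingError(ValueError):
    """Requested features do not fit in the genome without overlap."""


@dataclass
class GenomeAnnotation:
    """Chromosomes plus the genomic features every pipeline stage consumes.

    Attributes
    ----------
    chromosomes
        List of ``(name, length_bp)`` pairs.
    genes
        DataFrame with columns ``id, chrom, start, end, strand, tss``.
    origins
        DataFrame with columns ``id, chrom, pos, licensed``.
    centromeres
        Mapping chromosome name -> centromere position (bp).
    telomere_margin
        Distance from either chromosome end defining the telomeric zones.
    tf_sites
        DataFrame with columns ``tf, chrom, pos, strand``.
    """

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame
    origins: pd.DataFrame
    centromeres: dict[str, int]
    telomere_margin: int
    tf_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TF_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.validate()

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_length(self, name: str) -> int:
        return self.chrom_lengths[name]

    def validate(self) -> None:
        if self.telomere_margin <= 0:
            raise ValueError("telomere_margin must be > 0")
        lengths = self.chrom_lengths
        for _, g in self.genes.iterrows():
            L = lengths[g["chrom"]]
            if not (0 <= g["start"] < g["end"] <= L):
                raise ValueError(f"gene {g['id']} outside chromosome bounds")
            expected_tss = g["start"] if g["strand"] == "+" else g["end"]
            if g["tss"] != expected_tss:
                raise ValueError(f"gene {g['id']} TSS inconsistent with strand")

    def telomeric_zones(self, chrom: str) -> list[tuple[int, int]]:
        """Half-open intervals within ``telomere_margin`` of either end."""
        L = self.chrom_length(chrom)
        m = self.telomere_margin
        if 2 * m >= L:
            return [(0, L)]
        return [(0, m), (L - m, L)]

    def is_telomeric(self, chrom: str, start: int, end: int) -> bool:
        """Does the half-open interval overlap a telomeric zone?"""
        return any(start < z1 and end > z0 for z0, z1 in self.telomeric_zones(chrom))


@dataclass
class AnnotationConfig:
    """Sizes and counts for a synthetic annotation.

    ``tf_site_fraction`` of genes get one TF site placed 100-900 bp
    upstream of their TSS (inside the 1-kb promoter window used by the
    footprint pipeline); site names cycle through ``tf_names``.
    """

    chromosome_lengths: tuple[int, ...] = (200_000,)
    n_genes: int = 50
    n_origins: int = 10
    gene_length_range: tuple[int, int] = (800, 2_500)
    telomere_margin: int = 50_000
    tf_names: tuple[str, ...] = ("UME6", "REB1", "ABF1", "RAP1")
    tf_site_fraction: float = 0.5
    min_gene_gap: int = 200
    seed: int = 0


def _pack_intervals(
    length: int, sizes: np.ndarray, min_gap: int, rng: np.random.Generator
) -> np.ndarray:
    """Random non-overlapping starts for intervals of the given sizes."""
    n = len(sizes)
    if n == 0:
        return np.empty(0, dtype=int)
    occupied = int(sizes.sum()) + min_gap * (n - 1)
    free = length - occupied
    if free < 0:
        raise InfeasiblePackingError(
            f"{n} features of total {int(sizes.sum())} bp do not fit in {length} bp"
        )
    # spread the free space over the n+1 gaps uniformly at random
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += gaps[i]
        starts[i] = pos
        pos += sizes[i] + min_gap
    return starts


def make_genome_annotation(config: AnnotationConfig) -> GenomeAnnotation:
    """Generate a deterministic synthetic annotation from sizes and a seed.

    Genes are packed without overlap per chromosome (raising
    :class:`InfeasiblePackingError` when they cannot fit), strands are
    random, origins are quasi-evenly spaced with jitter, and the
    centromere sits mid-chromosome.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [(f"chr{i + 1}", int(L)) for i, L in enumerate(config.chromosome_lengths)]
    total_len = sum(L for _, L in chroms)

    # allocate gene counts per chromosome proportionally to length
    quota = np.array([L / total_len for _, L in chroms])
    counts = np.floor(quota * config.n_genes).astype(int)
    for i in range(config.n_genes - counts.sum()):
        counts[i % len(chroms)] += 1

    gene_rows: list[dict] = []
    gi = 0
    for (name, L), n_c in zip(chroms, counts):
        lo, hi = config.gene_length_range
        sizes = rng.integers(lo, hi + 1, size=n_c)
        starts = _pack_intervals(L, sizes, config.min_gene_gap, rng)
        strands = rng.choice(["+", "-"], size=n_c)
        for s, size, strand in zip(starts, sizes, strands):
            start, end = int(s), int(s + size)
            gene_rows.append(
                {
                    "id": f"gene{gi:04d}",
                    "chrom": name,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": start if strand == "+" else end,
                }
            )
            gi += 1
    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)

    # origins: evenly spaced anchors with jitter, allocated like genes
    o_counts = np.floor(quota * config.n_origins).astype(int)
    for i in range(config.n_origins - o_counts.sum()):
        o_counts[i % len(chroms)] += 1
    origin_rows: list[dict] = []
    oi = 0
    for (name, L), n_o in zip(chroms, o_counts):
        if n_o == 0:
            continue
        anchors = (np.arange(n_o) + 0.5) / n_o * L
        jitter = rng.uniform(-0.25, 0.25, size=n_o) * (L / max(n_o, 1))
        positions = np.clip((anchors + jitter).astype(int), 0, L - 1)
        for p in positions:
            origin_rows.append(
                {"id": f"ARS{oi + 1:03d}", "chrom": name, "pos": int(p), "licensed": True}
            )
            oi += 1
    origins = pd.DataFrame(origin_rows, columns=ORIGIN_COLUMNS)

    centromeres = {name: L // 2 for name, L in chroms}

    # TF sites upstream of a random subset of genes
    tf_rows: list[dict] = []
    if len(genes) and config.tf_site_fraction > 0:
        n_sites = int(round(config.tf_site_fraction * len(genes)))
        chosen = rng.choice(len(genes), size=n_sites, replace=False)
        for j, idx in enumerate(sorted(chosen)):
            g = genes.iloc[idx]
            d = int(rng.integers(100, 900))
            pos = g["tss"] - d if g["strand"] == "+" else g["tss"] + d
            L = dict(chroms)[g["chrom"]]
            pos = int(np.clip(pos, 0, L - 1))
            tf_rows.append(
                {
                    "tf": config.tf_names[j % len(config.tf_names)],
                    "chrom": g["chrom"],
                    "pos": pos,
                    "strand": g["strand"],
                }
            )
    tf_sites = pd.DataFrame(tf_rows, columns=TF_COLUMNS)

    return GenomeAnnotation(
        chromosomes=chroms,
        genes=genes,
        origins=origins,
        centromeres=centromeres,
        telomere_margin=config.telomere_margin,
        tf_sites=tf_sites,
    )
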