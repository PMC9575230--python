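"""End-to-end demo pipeline tying the stages into one reproducible run.

``run_pipeline`` simulates a two-strain study (replication timecourse,
expression timecourse, MNase fragments, mutant compendium) at desk
scale and runs every analysis stage in dependency order, writing TSV /
bedGraph / BED artifacts plus a resolved-config copy to the output
directory. Identical config + seed gives identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compendium as comp
from . import expression as xp
from . import footprints as fp
from . import io as rio
from . import nucleosomes as nuc
from . import replication as rt
from .annotation import AnnotationConfig, make_genome_annotation
from .sim import (
    CompendiumSimConfig,
    ExpressionSimConfig,
    FragmentSimConfig,
    ReplicationSimConfig,
    simulate_compendium,
    simulate_expression_counts,
    simulate_mnase_fragments,
    simulate_replication_counts,
)
from .sim.replication import advanced_firing_times, default_firing_times

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the full demo run."""

    out_dir: str = "repliscape_run"
    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (120_000, 120_000)
    n_genes: int = 60
    n_origins: int = 10
    bin_size: int = 1000
    smooth_window: int = 15
    n_expr_genes: int = 600
    k_clusters: int = 6
    fdr: float = 0.01
    n_mutants: int = 20
    n_similar: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = rio.load_config(path, schema=cls)
        return cls(**cfg)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run simulate -> trep / de / nuc / footprint -> compendium."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_resolved_config(asdict(cfg), out / "resolved_config.yaml")

    ann = make_genome_annotation(
        AnnotationConfig(
            chromosome_lengths=cfg.chromosome_lengths,
            n_genes=cfg.n_genes,
            n_origins=cfg.n_origins,
            telomere_margin=min(50_000, min(cfg.chromosome_lengths) // 3),
            seed=cfg.seed,
        )
    )
    rio.write_bed(
        ann.genes.rename(columns={"id": "name"}).assign(score=0), out / "genes.bed"
    )

    # --- replication timecourse ---
    control_mu = default_firing_times(ann)
    rep_cfg = ReplicationSimConfig(
        firing_mean={"control": control_mu,
                     "early": advanced_firing_times(control_mu)},
        bin_size=cfg.bin_size,
        seed=cfg.seed + 1,
    )
    rep = simulate_replication_counts(ann, rep_cfg)
    chroms = rep.bins["chrom"].to_numpy()
    origin_rows = []
    for cond in rep.conditions:
        cn = rt.compute_copy_number(
            rep.counts[cond], rep.g1_counts[cond], rep.bulk[cond],
            bins=rep.bins, timepoints=rep.timepoints,
        )
        prof = rt.fit_trep_profile(cn)
        prof.smoothed = rt.smooth_profile(prof.trep, cfg.smooth_window, chroms=chroms)
        rio.write_bedgraph(rep.bins, prof.trep, out / f"trep_{cond}.bedgraph")
        rio.write_bedgraph(rep.bins, prof.smoothed,
                           out / f"trep_{cond}_smoothed.bedgraph")
        for name, _ in ann.chromosomes:
            on = np.flatnonzero(chroms == name)
            for call in rt.call_origins_terminations(prof.smoothed[on]):
                b = rep.bins.iloc[on[call.index]]
                origin_rows.append({"chrom": b["chrom"], "start": b["start"],
                                    "end": b["end"],
                                    "name": f"{cond}_{call.kind}",
                                    "score": round(call.trep, 2)})
    rio.write_bed(pd.DataFrame(origin_rows), out / "origin_calls.bed")

    # --- expression timecourse ---
    expr_cfg = ExpressionSimConfig(n_genes=cfg.n_expr_genes, seed=cfg.seed + 2)
    cm, truth = simulate_expression_counts(None, expr_cfg)
    sf = xp.estimate_size_factors(cm.counts)
    disp = xp.estimate_dispersions(cm, sf)
    lrt = xp.test_timecourse(cm, size_factors=sf, dispersions=disp, fdr=cfg.fdr)
    de_genes = list(lrt.index[lrt["de"]])
    timepoints = sorted(cm.samples["timepoint"].unique())
    lfc = pd.DataFrame(
        {t: xp.test_per_timepoint(cm, t, size_factors=sf, dispersions=disp,
                                  fdr=cfg.fdr)["log2fc"] for t in timepoints}
    )
    rio.write_counts_tsv(lrt, out / "de_timecourse.tsv")
    rio.write_counts_tsv(lfc, out / "log2fc_per_timepoint.tsv")

    clusters = None
    if len(de_genes) >= cfg.k_clusters:
        clusters = xp.cluster_profiles(lfc.loc[de_genes], k=cfg.k_clusters,
                                       seed=cfg.seed)
        clusters.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")

    avg = xp.average_fold_change(lfc)
    avg.to_frame().to_csv(out / "avg_log2fc.tsv", sep="\t")

    # --- compendium screen ---
    if clusters is not None:
        groups = clusters.as_series(cm.counts.index)
        # similar mutants mimic the reference's per-cluster effect pattern
        cluster_means = {
            lab: float(np.sign(avg.reindex(groups.index[groups == lab]).median())
                       * max(1.5, abs(avg.reindex(groups.index[groups == lab]).median())))
            for lab in groups.unique() if lab != "non-DE"
        }
        comp_table, comp_truth = simulate_compendium(
            CompendiumSimConfig(n_mutants=cfg.n_mutants, n_similar=cfg.n_similar,
                                cluster_means=cluster_means, seed=cfg.seed + 3),
            groups,
        )
        screen = comp.screen_compendium(comp_table, groups, reference=avg,
                                        seed=cfg.seed)
        screen.table.to_csv(out / "compendium_screen.tsv", sep="\t")

    # --- nucleosomes & footprints (single pair of samples at desk scale) ---
    frag_tps = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    frag_cfg = FragmentSimConfig(
        conditions=("control", "early"),
        timepoints=frag_tps,
        jitter_sd_by_sample={("early", 20.0): 40.0, ("early", 30.0): 40.0},
        tf_occupancy=0.9,
        # the exemplar repressor footprint is lost during S-phase in the
        # global-early strain only
        tf_occupancy_by_name={"UME6": {
            ("early", t): (0.3 if 0 < t < 60 else 0.9) for t in frag_tps
        }},
        seed=cfg.seed + 4,
    )
    frags = simulate_mnase_fragments(ann, frag_cfg)
    plus_one = {}
    for key, df in frags.items():
        cov = nuc.dyad_coverage(df, ann.chrom_lengths)
        calls = nuc.call_nucleosomes(cov)
        plus_one[f"{key[0]}_t{key[1]:g}"] = nuc.identify_plus_one(calls, ann.genes)
    nuc.plus_one_offset_matrix(plus_one).to_csv(out / "plus_one_offsets.tsv", sep="\t")

    sub = {k: fp.select_subnucleosomal(df) for k, df in frags.items()}
    sub = fp.size_matched_downsample(sub, seed=cfg.seed)
    pooled = pd.concat(sub.values(), ignore_index=True)
    peaks = fp.call_peaks_merged(fp.fragment_coverage(pooled, ann.chrom_lengths))
    if len(peaks):
        counts = fp.peak_sample_counts(peaks, sub)
        conf = fp.filter_high_confidence(counts)
        meta = pd.DataFrame(
            [{"sample": f"{c}_t{t:g}", "strain": c, "timepoint": t}
             for c, t in sub], ).set_index("sample")
        counts.columns = [f"{c}_t{t:g}" for c, t in counts.columns]
        flagged = fp.differential_peaks(
            peaks, counts, meta, ann.genes, control="control", treatment="early")
        flagged = fp.annotate_to_tf_sites(flagged, ann.tf_sites)
        flagged["sum_log2"] = conf["sum_log2"]
        flagged["high_confidence"] = conf["high_confidence"]
        flagged.to_csv(out / "subnuc_peaks.tsv", sep="\t", index=False)
        summary = fp.tf_effect_ratios(flagged, de_genes)
        summary.per_tf.to_csv(out / "tf_summary.tsv", sep="\t")

    return out
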