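# repliscape

Analytics for asking what the *timing* of DNA replication does to gene
expression and chromatin in a single budding-yeast cell cycle.

When the limiting replication-initiation factors (Sld2, Sld3, Dpb11,
Dbf4, Cdc45, Sld7 — "SSDDCS") are conditionally over-expressed, most
origins fire at the very start of S-phase instead of across it. Probing
the consequences requires a chain of quantitative machinery, and this
package implements that chain as a tested, reusable library:

* **Replication timing** — per-1-kb-bin copy-number ratios from
  sequencing timecourses, bulk-normalized; a bounded 4-parameter
  logistic fit per bin with *T*\_rep defined as the time of half-maximal
  replication (ratio = 1.5); moving-average profiles; origin
  (local-minimum) and termination (local-maximum) calls; quintile and
  telomere/centromere summaries.
* **Expression timecourse** — median-of-ratios size factors, per-gene NB
  dispersion, per-timepoint Wald tests and a timecourse likelihood-ratio
  test (strain × timepoint vs timepoint means, post-G1 only) at
  FDR < 0.01; seeded k-means (k = 6) on row z-scored profiles; exact
  binomial cluster enrichment; time-averaged fold-changes;
  Holm-corrected rank-sum group comparisons against random non-DE genes.
* **Nucleosome dynamics** — dyad coverage from 140–180 bp fragments, a
  greedy nucleosome caller, +1 classification in the −20..+80 bp TSS
  window, and an autocorrelation (ACF) phasing score for the first four
  gene-body nucleosomes (genes > 700 bp).
* **TF footprints** — sub-nucleosomal (< 100 bp) fragment selection,
  size-matched downsampling, merged peak calling, the
  sum-log2-normalized-reads > 75 confidence filter, the 2-fold-outside-G1
  + 1-kb-promoter differential rule, 200-bp TF-site annotation, per-TF
  binding-change vs expression-effect ratios, and PWM motif scanning
  (MEME minimal input).
* **Compendium screen** — per-mutant Kruskal–Wallis tests of a
  fold-change compendium against the expression clusters, with
  η² = (H − k + 1)/(n − k) effect sizes and Bonferroni 0.001 / η² ≥ 0.14
  similarity calls.
* **Simulators** — seeded generators for every input (origin-firing /
  fork-progression copy-number timecourses, NB expression counts with
  cluster-structured effects, phased MNase fragment sets with TF
  footprints, mutant compendia) that also return their ground truth, so
  every stage is validated by parameter recovery.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The `simulate` subcommand generates a two-strain study at desk scale and
runs every stage:

```bash
repliscape simulate --out demo --seed 1
```

which prints `wrote artifacts to demo` and leaves, among others:

* `trep_control_smoothed.bedgraph` — the smoothed *T*\_rep track, e.g.
  `chr1  0  1000  34.9127`: the first kilobase of chr1 replicates
  ~34.9 min after G1 release in the control strain (telomere-proximal,
  hence late);
* `de_timecourse.tsv` — the timecourse LRT: 171 of 600 simulated genes
  DE at FDR < 0.01, matching the simulation's built-in DE fraction;
* `clusters.tsv` — k-means assignment of the DE genes into six clusters
  of 27–30 genes;
* `subnuc_peaks.tsv` — 30 sub-nucleosomal peaks, all high-confidence;
  8 differential, all at UME6 sites (the simulated repressor footprint
  that is lost during S-phase in the global-early strain), e.g.
  `chr1 1742 1861 UME6 gene0000` with a maximal post-G1
  |log2 ratio| of 1.55;
* `tf_summary.tsv` — the per-TF two-ratio table: UME6 at
  x = 1.0 (8/8 peaks changed), y = 0.625 (5/8 changed peaks in DE-gene
  promoters); the unperturbed TFs at x = 0;
* `compendium_screen.tsv` — the Kruskal–Wallis screen flags exactly the
  3 simulated "similar" mutants of 20 (e.g. mut013: H = 326.5,
  Bonferroni p ≈ 0, η² = 0.69, sign agreement 1.0).

Every stage is also importable directly, e.g.

```python
import numpy as np
from repliscape import fit_trep

t = np.arange(0, 65, 5, dtype=float)
fit = fit_trep(t, 1 + 1 / (1 + np.exp(-0.5 * (t - 25))))
fit.trep            # 25.0 — minutes after G1 release
fit.predict(fit.trep)  # 1.5 — half-maximal by construction
```

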