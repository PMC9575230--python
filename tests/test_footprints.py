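"""Sub-nucleosomal footprint pipeline: selection, downsampling, peaks,
confidence/differential filters, TF annotation, motif scanning."""

import numpy as np
import pandas as pd
import pytest

from repliscape import footprints as fp
from repliscape.motifs import PWM, pwm_scan, read_meme


def frags(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


class TestSelection:
    def test_strictly_below_100bp(self):
        df = frags([("chr1", 0, 80), ("chr1", 0, 99), ("chr1", 0, 100),
                    ("chr1", 0, 120)])
        out = fp.select_subnucleosomal(df)
        assert sorted(out["end"]) == [80, 99]

    def test_empty_input_passes_through(self):
        out = fp.select_subnucleosomal(frags([]))
        assert len(out) == 0


class TestDownsampling:
    def sets_with_counts(self, counts_by_sample, length=50):
        out = {}
        for name, n in counts_by_sample.items():
            out[name] = frags([("chr1", 100 * i, 100 * i + length)
                               for i in range(n)])
        return out

    def test_min_rule_per_length(self):
        sets = self.sets_with_counts({"a": 10, "b": 7, "c": 12})
        down = fp.size_matched_downsample(sets, seed=0)
        assert all(len(df) == 7 for df in down.values())

    def test_histograms_identical_across_samples_afterwards(self, rng):
        sets = {}
        for name in "abc":
            n = rng.integers(100, 200)
            lengths = rng.integers(20, 100, n)
            starts = rng.integers(0, 5000, n)
            sets[name] = frags([("chr1", s, s + l)
                                for s, l in zip(starts, lengths)])
        down = fp.size_matched_downsample(sets, seed=1)
        hists = [np.bincount((df["end"] - df["start"]).to_numpy(), minlength=100)
                 for df in down.values()]
        for h in hists[1:]:
            assert np.array_equal(hists[0], h)

    def test_identical_inputs_are_unchanged_and_seeded_runs_reproduce(self):
        sets = self.sets_with_counts({"a": 9, "b": 9})
        down1 = fp.size_matched_downsample(sets, seed=3)
        down2 = fp.size_matched_downsample(sets, seed=3)
        for k in sets:
            assert len(down1[k]) == 9
            pd.testing.assert_frame_equal(down1[k], down2[k])


class TestPeakCalling:
    def test_single_run_above_threshold(self):
        cov = {"chr1": np.array([0.0, 0, 3, 4, 3, 0])}
        peaks = fp.call_peaks_merged(cov, min_coverage=2, merge_gap=1)
        assert len(peaks) == 1
        assert (peaks.loc[0, "start"], peaks.loc[0, "end"]) == (2, 5)

    def test_nearby_runs_merged(self):
        cov = np.zeros(100)
        cov[10:20] = 5
        cov[25:35] = 5
        peaks = fp.call_peaks_merged({"chr1": cov}, min_coverage=2, merge_gap=10)
        assert len(peaks) == 1
        assert (peaks.loc[0, "start"], peaks.loc[0, "end"]) == (10, 35)
        # with a smaller gap they stay separate
        peaks2 = fp.call_peaks_merged({"chr1": cov}, min_coverage=2, merge_gap=5)
        assert len(peaks2) == 2

    def test_threshold_above_maximum_gives_no_peaks(self):
        cov = {"chr1": np.array([0.0, 1, 2, 1, 0])}
        assert len(fp.call_peaks_merged(cov, min_coverage=10)) == 0


class TestConfidenceFilter:
    def test_boundary_is_strict(self):
        kept = pd.DataFrame({f"s{i}": [8.0] for i in range(26)})
        dropped = pd.DataFrame({f"s{i}": [8.0] for i in range(25)})
        a = fp.filter_high_confidence(kept, pseudocount=0.0)
        b = fp.filter_high_confidence(dropped, pseudocount=0.0)
        assert a.loc[0, "sum_log2"] == pytest.approx(78.0)
        assert bool(a.loc[0, "high_confidence"])
        assert b.loc[0, "sum_log2"] == pytest.approx(75.0)
        assert not bool(b.loc[0, "high_confidence"])

    def test_zero_counts_contribute_zero_with_unit_pseudocount(self):
        df = pd.DataFrame({"s0": [0.0], "s1": [8.0]})
        res = fp.filter_high_confidence(df, pseudocount=1.0)
        assert res.loc[0, "sum_log2"] == pytest.approx(np.log2(9.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fp.filter_high_confidence(pd.DataFrame({"s": [-1.0]}))


def simple_genes():
    return pd.DataFrame([
        {"id": "gp", "chrom": "chr1", "start": 5000, "end": 7000,
         "strand": "+", "tss": 5000},
    ])


def diff_setup(peak_start, ratios_by_tp):
    """One peak + synthetic normalized counts realizing given log2 ratios."""
    peaks = pd.DataFrame([{"chrom": "chr1", "start": peak_start,
                           "end": peak_start + 100}])
    cols, meta_rows = {}, []
    for t, r in ratios_by_tp.items():
        base = 100.0
        cols[f"control_t{t:g}"] = [base]
        cols[f"early_t{t:g}"] = [(base + 1) * 2.0**r - 1]
        meta_rows += [
            {"sample": f"control_t{t:g}", "strain": "control", "timepoint": t},
            {"sample": f"early_t{t:g}", "strain": "early", "timepoint": t},
        ]
    counts = pd.DataFrame(cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return peaks, counts, meta


class TestDifferential:
    def test_promoter_peak_with_2fold_post_g1_is_differential(self):
        peaks, counts, meta = diff_setup(4450, {0.0: 0.0, 25.0: 1.1})
        out = fp.differential_peaks(peaks, counts, meta, simple_genes())
        assert out.loc[0, "promoter_gene"] == "gp"
        assert bool(out.loc[0, "differential"])

    def test_g1_only_change_is_not_differential(self):
        peaks, counts, meta = diff_setup(4450, {0.0: 3.0, 25.0: 0.0})
        out = fp.differential_peaks(peaks, counts, meta, simple_genes())
        assert not bool(out.loc[0, "differential"])

    def test_distal_peak_fails_the_location_filter(self):
        peaks, counts, meta = diff_setup(3450, {0.0: 0.0, 25.0: 3.0})
        out = fp.differential_peaks(peaks, counts, meta, simple_genes())
        assert out.loc[0, "promoter_gene"] is None
        assert not bool(out.loc[0, "differential"])


class TestTFAnnotation:
    def sites(self, rows):
        return pd.DataFrame(rows, columns=["tf", "chrom", "pos", "strand"])

    def peak_at(self, center):
        return pd.DataFrame([{"chrom": "chr1", "start": center - 50,
                              "end": center + 50}])

    def test_200bp_is_inclusive_201_is_not(self):
        sites = self.sites([("X", "chr1", 5200, "+")])
        a = fp.annotate_to_tf_sites(self.peak_at(5000), sites)
        b = fp.annotate_to_tf_sites(self.peak_at(4999), sites)
        assert a.loc[0, "tf"] == "X"
        assert b.loc[0, "tf"] is None

    def test_nearest_site_wins_and_exact_tie_is_lexical(self):
        sites = self.sites([("B", "chr1", 5100, "+"), ("A", "chr1", 4880, "+")])
        out = fp.annotate_to_tf_sites(self.peak_at(5000), sites)
        assert out.loc[0, "tf"] == "B"  # 100 < 120
        tied = self.sites([("D", "chr1", 5100, "+"), ("C", "chr1", 4900, "+")])
        out2 = fp.annotate_to_tf_sites(self.peak_at(5000), tied)
        assert out2.loc[0, "tf"] == "C"


class TestTFRatios:
    def peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf",
                                           "differential", "promoter_gene"])

    def test_hand_counted_ratios(self):
        rows = [("chr1", i * 1000, i * 1000 + 100, "X", d, g) for i, (d, g) in
                enumerate([(True, "de1"), (True, "other"), (False, None),
                           (False, None)])]
        res = fp.tf_effect_ratios(self.peaks(rows), de_genes={"de1"})
        assert res.per_tf.loc["X", "x_ratio"] == pytest.approx(0.5)
        assert res.per_tf.loc["X", "y_ratio"] == pytest.approx(0.5)

    def test_no_differential_peaks_leaves_y_undefined(self):
        rows = [("chr1", 0, 100, "X", False, None)]
        res = fp.tf_effect_ratios(self.peaks(rows), de_genes=set())
        assert res.per_tf.loc["X", "x_ratio"] == 0.0
        assert np.isnan(res.per_tf.loc["X", "y_ratio"])

    def test_fully_differential_in_de_promoters_gives_unit_ratios(self):
        rows = [("chr1", 0, 100, "X", True, "de1"),
                ("chr1", 500, 600, "X", True, "de1")]
        res = fp.tf_effect_ratios(self.peaks(rows), de_genes={"de1"})
        assert res.per_tf.loc["X", "x_ratio"] == 1.0
        assert res.per_tf.loc["X", "y_ratio"] == 1.0


class TestPWMScan:
    def planted_pwm(self, motif="ACGTA"):
        lo = np.full((len(motif), 4), -2.0)
        for i, b in enumerate(motif):
            lo[i, "ACGT".index(b)] = 2.0
        return PWM(name="m", log_odds=lo)

    def test_planted_motif_found_at_exact_positions_at_max_score(self):
        pwm = self.planted_pwm("ACGTA")
        seq = "TT" + "ACGTA" + "GGGG" + "ACGTA" + "CC"
        hits = pwm_scan({"chr1": seq}, pwm, threshold=pwm.max_score)
        fwd = hits[hits["strand"] == "+"]
        assert sorted(fwd["start"]) == [2, 11]

    def test_uniform_pwm_with_positive_threshold_finds_nothing(self):
        pwm = PWM(name="u", log_odds=np.zeros((4, 4)))
        hits = pwm_scan({"chr1": "ACGTACGTACGT"}, pwm, threshold=0.5)
        assert len(hits) == 0

    def test_reverse_complement_swaps_strands_preserves_count(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 300))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        pwm = self.planted_pwm("ACGTAC")
        h1 = pwm_scan({"c": seq}, pwm, threshold=6.0)
        h2 = pwm_scan({"c": rc}, pwm, threshold=6.0)
        assert len(h1) == len(h2)
        assert sorted(h1["strand"]) == sorted(
            {"+": "-", "-": "+"}[s] for s in h2["strand"])

    def test_meme_minimal_round_trip(self, tmp_path):
        meme = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF TEST
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
 0.970 0.010 0.010 0.010
 0.010 0.970 0.010 0.010
 0.010 0.010 0.010 0.970
"""
        path = tmp_path / "m.meme"
        path.write_text(meme)
        pwms = read_meme(path)
        assert len(pwms) == 1 and len(pwms[0]) == 3
        hits = pwm_scan({"s": "GGACTGG"}, pwms[0],
                        threshold=0.9 * pwms[0].max_score)
        assert ((hits["start"] == 2) & (hits["strand"] == "+")).any()
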