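"""Size factors, NB Wald/LRT, clustering, enrichment, group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from repliscape import expression as xp
from repliscape.sim import ExpressionSimConfig, simulate_expression_counts


def make_cm(counts: np.ndarray, strains, timepoints, reps=None) -> xp.CountMatrix:
    names = [f"s{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(counts, columns=names,
                      index=[f"g{i}" for i in range(counts.shape[0])])
    meta = pd.DataFrame({
        "sample": names, "strain": strains, "timepoint": timepoints,
        "replicate": reps or [1] * len(names),
    }).set_index("sample")
    return xp.CountMatrix(counts=df, samples=meta)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(xp.estimate_size_factors(c), 1.0)

    def test_doubled_sample_splits_the_ratio_geometrically(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = xp.estimate_size_factors(c)
        assert sf["a"] == pytest.approx(1 / math.sqrt(2))
        assert sf["b"] == pytest.approx(math.sqrt(2))

    def test_single_sample_factor_is_one(self):
        c = pd.DataFrame({"a": [10, 20, 30]})
        assert xp.estimate_size_factors(c)["a"] == pytest.approx(1.0)

    def test_scaling_one_sample_scales_its_relative_factor(self):
        # the geometric-mean reference shifts by c^(1/m), so the exact
        # invariance is on factor ratios: sf_b/sf_a gains a factor of c
        rng = np.random.default_rng(1)
        c = pd.DataFrame(rng.poisson(100, size=(50, 3)) + 1, columns=list("abc"))
        sf = xp.estimate_size_factors(c)
        c2 = c.copy()
        c2["b"] = c2["b"] * 3
        sf2 = xp.estimate_size_factors(c2)
        assert (sf2["b"] / sf2["a"]) / (sf["b"] / sf["a"]) == \
            pytest.approx(3.0, rel=1e-6)

    def test_agrees_with_reference_median_of_ratios_implementation(self):
        # independent oracle: the published DESeq2-style normalization
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(9)
        c = pd.DataFrame(rng.poisson(120, size=(60, 5)) + 1,
                         columns=[f"s{i}" for i in range(5)])
        _, ref = deseq2_norm(c.T)  # pydeseq2 takes samples x genes
        assert np.allclose(xp.estimate_size_factors(c).to_numpy(), ref)

    def test_no_universally_expressed_gene_rejected(self):
        c = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError):
            xp.estimate_size_factors(c)


@pytest.fixture(scope="module")
def null_sim():
    cfg = ExpressionSimConfig(n_genes=2000, frac_de=0.0, seed=11)
    return simulate_expression_counts(None, cfg)


class TestWald:
    def test_identical_gene_has_zero_lfc_and_flat_p(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(200, size=(20, 2))
        counts = np.hstack([base, base])  # treatment == control exactly
        cm = make_cm(counts, ["control"] * 2 + ["treatment"] * 2, [10.0] * 4,
                     [1, 2, 1, 2])
        res = xp.test_per_timepoint(cm, 10.0)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_type_i_error_is_nominal_on_null_simulation(self, null_sim):
        cm, _ = null_sim
        res = xp.test_per_timepoint(cm, 20.0)
        assert (res["pvalue"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        assert res["de"].sum() <= 5  # essentially nothing at FDR 0.01

    def test_missing_timepoint_rejected(self, null_sim):
        cm, _ = null_sim
        with pytest.raises(ValueError):
            xp.test_per_timepoint(cm, 999.0)


class TestTimecourseLRT:
    def test_flat_gene_is_not_significant_and_g1_difference_ignored(self):
        rng = np.random.default_rng(3)
        times = [0.0, 10.0, 20.0]
        strains = ["control"] * 6 + ["treatment"] * 6
        tps = [t for t in times for _ in range(2)] * 2
        reps = [1, 2] * 6
        flat = rng.poisson(200, size=12).reshape(1, 12)
        g1_only = flat.copy()
        # double the treatment counts at G1 only
        for j, (s, t) in enumerate(zip(strains, tps)):
            if s == "treatment" and t == 0.0:
                g1_only[0, j] *= 2
        filler = rng.poisson(150, size=(30, 12))
        counts = np.vstack([flat, g1_only, filler])
        cm = make_cm(counts, strains, tps, reps)
        res = xp.test_timecourse(cm)
        assert res["pvalue"].iloc[0] > 0.2
        assert res["pvalue"].iloc[1] > 0.05  # G1-only difference: not a hit

    def test_marker_genes_are_excluded_before_testing(self, null_sim):
        cm, _ = null_sim
        excluded = list(cm.counts.index[:6])
        res = xp.test_timecourse(cm, excluded_genes=excluded)
        assert not set(excluded) & set(res.index)

    def test_separable_signal_is_detected(self):
        traj = np.zeros((6, 4))
        traj[:, 1:] = 2.0
        cfg = ExpressionSimConfig(n_genes=400, frac_de=0.25,
                                  timepoints=(0, 10, 20, 30),
                                  trajectories=traj, seed=12)
        cm, truth = simulate_expression_counts(None, cfg)
        res = xp.test_timecourse(cm)
        is_de = truth["cluster"] != "non-DE"
        assert res.loc[is_de, "de"].mean() > 0.95


class TestClustering:
    def make_profiles(self, sep=6.0, n=120, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, sep, size=(3, 8))
        labels = np.repeat([0, 1, 2], n // 3)
        x = centers[labels] + rng.normal(0, 1.0, size=(n, 8))
        return pd.DataFrame(x, index=[f"g{i}" for i in range(n)]), labels

    def test_recovers_well_separated_groups_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        mat, truth = self.make_profiles(sep=8.0)
        ca = xp.cluster_profiles(mat, k=3, seed=0)
        assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0

    def test_k_one_puts_everything_in_one_cluster(self):
        mat, _ = self.make_profiles()
        ca = xp.cluster_profiles(mat, k=1, seed=0)
        assert set(ca.labels) == {1}

    def test_same_seed_gives_identical_assignment(self):
        mat, _ = self.make_profiles()
        a = xp.cluster_profiles(mat, k=3, seed=5)
        b = xp.cluster_profiles(mat, k=3, seed=5)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_constant_rows_dropped_with_warning(self):
        mat, _ = self.make_profiles()
        mat.iloc[0] = 7.0
        with pytest.warns(UserWarning):
            ca = xp.cluster_profiles(mat, k=3, seed=0)
        assert mat.index[0] in ca.dropped
        assert mat.index[0] not in ca.labels.index


def exact_binomial_tail(n, p, K, upper):
    """Independent oracle: direct summation of binomial pmf terms."""
    total = 0.0
    rng_range = range(K, n + 1) if upper else range(0, K + 1)
    for j in rng_range:
        total += math.comb(n, j) * p**j * (1 - p) ** (n - j)
    return total


class TestEnrichment:
    def test_half_background_hand_value(self):
        genes = [f"g{i}" for i in range(10)]
        annotated = genes[:5] + [f"x{i}" for i in range(495)]
        direction, p = xp.cluster_enrichment(genes, annotated, 1000)
        assert p == pytest.approx(0.623, abs=5e-4)

    @pytest.mark.parametrize("n,M,G,K", [
        (10, 500, 1000, 5), (20, 100, 1000, 6), (7, 300, 600, 7),
        (12, 50, 400, 0), (15, 200, 1000, 2), (20, 999, 1000, 20),
    ])
    def test_matches_exact_summation_oracle(self, n, M, G, K):
        cluster = [f"c{i}" for i in range(n)]
        annotated = cluster[:K] + [f"a{i}" for i in range(M - K)]
        direction, p = xp.cluster_enrichment(cluster, annotated, G)
        p_over = exact_binomial_tail(n, M / G, K, upper=True)
        p_under = exact_binomial_tail(n, M / G, K, upper=False)
        expected = min(p_over, p_under)
        assert p == pytest.approx(expected, abs=1e-12)
        assert direction == ("over" if p_over <= p_under else "under")

    def test_full_overlap_closed_form(self):
        cluster = [f"c{i}" for i in range(5)]
        annotated = cluster + [f"a{i}" for i in range(45)]
        _, p = xp.cluster_enrichment(cluster, annotated, 100)
        assert p == pytest.approx(0.5**5, abs=1e-12)

    def test_saturated_annotation_forces_p_one(self):
        cluster = [f"c{i}" for i in range(5)]
        annotated = cluster + [f"a{i}" for i in range(95)]
        direction, p = xp.cluster_enrichment(cluster, annotated, 100)
        assert p == pytest.approx(1.0)


class TestAveragesAndGroups:
    def test_average_fold_change_excludes_g1(self):
        lfc = pd.DataFrame({0.0: [5.0], 10.0: [0.0], 20.0: [2.0]}, index=["g"])
        assert xp.average_fold_change(lfc)["g"] == pytest.approx(1.0)

    def test_group_comparison_separated_and_matched_groups(self):
        rng = np.random.default_rng(7)
        values = pd.Series(rng.normal(0, 1, 800),
                           index=[f"g{i}" for i in range(800)])
        non_de = list(values.index[:400])
        same = list(values.index[400:500])
        shifted = list(values.index[500:600])
        values.loc[shifted] += 10.0
        res = xp.group_comparison(values, {"same": same, "shift": shifted},
                                  non_de, n_control=300, seed=0)
        assert res.loc["shift", "p_holm"] < 1e-10
        assert res.loc["same", "pvalue"] > 0.05
        assert (res["p_holm"].dropna() >= res["pvalue"].dropna()).all()

    def test_small_group_rejected(self):
        values = pd.Series(np.arange(400.0), index=[f"g{i}" for i in range(400)])
        with pytest.raises(ValueError):
            xp.group_comparison(values, {"tiny": ["g0"]}, list(values.index),
                                n_control=300, seed=0)
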