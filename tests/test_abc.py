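"""ABC scoring, fold-change propagation and ED50 stratification."""

import numpy as np
import pandas as pd
import pytest

from tfdose import (
    SimulationConfig,
    compute_abc_scores,
    generate_regulatory_architecture,
    predict_gene_fold_change,
    stratify_predicted_responses,
)


def _res(rows):
    return pd.DataFrame(rows, columns=["re_id", "chrom", "position",
                                       "baseline_atac", "baseline_k27ac"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


GENE = _genes([("g1", "chr1", 1_000_000)])


class TestScores:
    def test_equidistant_equal_activity_split_evenly(self):
        res = _res([("a", "chr1", 1_010_000, 4.0, 4.0),
                    ("b", "chr1", 990_000, 4.0, 4.0)])
        links = compute_abc_scores(res, GENE)
        assert np.allclose(links["abc_score"], 0.5)

    def test_distance_power_law_ratio(self):
        res = _res([("near", "chr1", 1_010_000, 2.0, 2.0),
                    ("far", "chr1", 1_100_000, 2.0, 2.0)])
        links = compute_abc_scores(res, GENE).set_index("re_id")
        ratio = links.loc["near", "abc_score"] / links.loc["far", "abc_score"]
        assert ratio == pytest.approx(10**0.7, rel=1e-9)

    def test_activity_is_geometric_mean(self):
        res = _res([("a", "chr1", 1_050_000, 4.0, 9.0)])
        links = compute_abc_scores(res, GENE)
        assert links["activity"].iloc[0] == pytest.approx(6.0)

    def test_promoter_re_excluded_and_scores_renormalize(self):
        res = _res([("prom", "chr1", 1_000_800, 5.0, 5.0),
                    ("a", "chr1", 1_050_000, 5.0, 5.0),
                    ("b", "chr1", 1_200_000, 5.0, 5.0)])
        links = compute_abc_scores(res, GENE)
        assert "prom" not in set(links["re_id"])
        assert links["abc_score"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_re_exactly_at_tss_excluded(self):
        res = _res([("zero", "chr1", 1_000_000, 5.0, 5.0),
                    ("a", "chr1", 1_050_000, 5.0, 5.0)])
        links = compute_abc_scores(res, GENE)
        assert set(links["re_id"]) == {"a"}

    def test_window_boundary_and_orphan_genes(self):
        res = _res([("inside", "chr1", 6_000_000, 5.0, 5.0),
                    ("outside", "chr1", 6_000_001, 5.0, 5.0)])
        genes = _genes([("g1", "chr1", 1_000_000), ("lonely", "chr2", 500)])
        links = compute_abc_scores(res, genes)
        assert set(links["re_id"]) == {"inside"}
        assert links.attrs["genes_without_links"] == ["lonely"]

    def test_negative_activity_rejected(self):
        res = _res([("a", "chr1", 1_050_000, -1.0, 5.0)])
        with pytest.raises(ValueError):
            compute_abc_scores(res, GENE)

    def test_scale_equivariance_and_monotone_contact(self):
        rng = np.random.default_rng(0)
        rows = [(f"r{i}", "chr1", 1_000_000 + int(p), a, k)
                for i, (p, a, k) in enumerate(zip(
                    rng.integers(2_000, 4_000_000, 20),
                    rng.uniform(1, 50, 20), rng.uniform(1, 50, 20)))]
        res = _res(rows)
        l1 = compute_abc_scores(res, GENE)
        res2 = res.assign(baseline_atac=res.baseline_atac * 7.3,
                          baseline_k27ac=res.baseline_k27ac * 7.3)
        l2 = compute_abc_scores(res2, GENE)
        assert np.allclose(l1["abc_score"], l2["abc_score"])
        # same activity, increasing distance -> strictly decreasing score
        res3 = _res([(f"d{i}", "chr1", 1_000_000 + p, 5.0, 5.0)
                     for i, p in enumerate([10_000, 50_000, 200_000, 1_000_000])])
        l3 = compute_abc_scores(res3, GENE)
        assert (np.diff(l3.sort_values("distance")["abc_score"]) < 0).all()


class TestPrediction:
    def test_weighted_mean_example(self):
        links = pd.DataFrame({"gene_id": ["g1", "g1"], "re_id": ["a", "b"],
                              "distance": [1e4, 1e5], "activity": [1, 1],
                              "contact": [1, 1], "abc_score": [0.75, 0.25]})
        fc = pd.DataFrame({"re_id": ["a", "b"], "condition": [50.0, 50.0],
                           "fc": [0.5, 1.0]})
        out = predict_gene_fold_change(links, fc, condition=50.0)
        assert out["predicted_fc"].iloc[0] == pytest.approx(0.625)

    def test_unit_fold_changes_predict_unity(self):
        cfg = SimulationConfig(seed=1)
        arch, re_fc, _ = generate_regulatory_architecture(cfg, 20, 3, gene_noise_sd=0.0)
        links = compute_abc_scores(arch["res"].assign(chrom=arch["chrom"]),
                                   arch["genes"].assign(chrom=arch["chrom"]))
        fc = pd.DataFrame({"re_id": arch["res"]["re_id"],
                           "condition": 100.0, "fc": 1.0})
        out = predict_gene_fold_change(links, fc, condition=100.0)
        assert np.allclose(out["predicted_fc"], 1.0)

    def test_noiseless_round_trip_exact(self):
        cfg = SimulationConfig(seed=3)
        arch, re_fc, gene_fc = generate_regulatory_architecture(
            cfg, 50, 4, gene_noise_sd=0.0)
        links = compute_abc_scores(arch["res"].assign(chrom=arch["chrom"]),
                                   arch["genes"].assign(chrom=arch["chrom"]))
        for cond in sorted(re_fc["condition"].unique()):
            pred = predict_gene_fold_change(links, re_fc, condition=cond)
            obs = gene_fc[gene_fc["condition"] == cond].set_index("gene_id")["fc"]
            merged = pred.set_index("gene_id")["predicted_fc"].reindex(obs.index)
            assert np.allclose(merged, obs, atol=1e-12, rtol=0)

    def test_missing_mass_flags_low_confidence(self):
        links = pd.DataFrame({"gene_id": ["g1"] * 3, "re_id": list("abc"),
                              "distance": [1e4] * 3, "activity": [1] * 3,
                              "contact": [1] * 3, "abc_score": [0.6, 0.3, 0.1]})
        fc = pd.DataFrame({"re_id": ["b", "c"], "condition": [50.0] * 2,
                           "fc": [0.5, 0.8]})
        out = predict_gene_fold_change(links, fc, condition=50.0)
        assert bool(out["low_confidence"].iloc[0])
        expected = (0.3 * 0.5 + 0.1 * 0.8) / 0.4
        assert out["predicted_fc"].iloc[0] == pytest.approx(expected)

    def test_nonpositive_fold_changes_rejected(self):
        links = pd.DataFrame({"gene_id": ["g1"], "re_id": ["a"], "distance": [1e4],
                              "activity": [1], "contact": [1], "abc_score": [1.0]})
        fc = pd.DataFrame({"re_id": ["a"], "condition": [50.0], "fc": [0.0]})
        with pytest.raises(ValueError):
            predict_gene_fold_change(links, fc, condition=50.0)


class TestStratification:
    def _responses(self, ed50s, seed=0):
        """Gene responses whose depth at each dosage follows each gene's own
        Hill curve; normalized log-response then reflects ED50."""
        rng = np.random.default_rng(seed)
        conds = [4.0, 18.0, 36.0, 51.0, 72.0, 100.0]
        rows = []
        for i, e in enumerate(ed50s):
            for c in conds:
                u = c**3 / (e**3 + c**3)
                u100 = 100.0**3 / (e**3 + 100.0**3)
                fc = np.exp(np.log(0.2) * (1 - u / u100))
                rows.append({"gene_id": f"g{i}", "condition": c, "fc": fc})
        return pd.DataFrame(rows)

    def test_identical_sides_identical_tables(self):
        ed50s = np.linspace(10, 90, 30)
        resp = self._responses(ed50s)
        ed = pd.Series(ed50s, index=[f"g{i}" for i in range(30)])
        t1, p1 = stratify_predicted_responses(resp, ed)
        t2, p2 = stratify_predicted_responses(resp.copy(), ed)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_ed50_bins_separate_at_intermediate_dosage(self):
        ed50s = np.linspace(10, 90, 60)
        resp = self._responses(ed50s)
        ed = pd.Series(ed50s, index=[f"g{i}" for i in range(60)])
        table, tests = stratify_predicted_responses(resp, ed)
        mid = table[table["condition"] == 51.0].set_index("bin")["median"]
        assert mid["buffered"] < mid["moderate"] < mid["high"]
        assert tests.loc[tests["condition"] == 51.0, "kruskal_p"].iloc[0] < 0.01

    def test_single_bin_gives_nan_p(self):
        ed50s = np.full(20, 35.0)
        resp = self._responses(ed50s)
        ed = pd.Series(ed50s, index=[f"g{i}" for i in range(20)])
        _, tests = stratify_predicted_responses(resp, ed)
        assert tests["kruskal_p"].isna().all()

    def test_boundary_ed50_binned_as_moderate(self):
        ed50s = np.array([30.0] * 5 + [10.0] * 5 + [80.0] * 5)
        resp = self._responses(ed50s)
        ed = pd.Series(ed50s, index=[f"g{i}" for i in range(15)])
        table, _ = stratify_predicted_responses(resp, ed)
        mod_n = table[(table["condition"] == 51.0) & (table["bin"] == "moderate")]["n"]
        assert mod_n.iloc[0] == 5
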