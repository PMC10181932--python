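"""Normalization, batch correction, scaling/outliers, dependent-feature calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfdose import (
    batch_correct,
    call_dependent_features,
    scale_and_filter,
    tmm_normalize,
    tmm_scale_factors,
)
from tfdose.preprocess import DoseSeriesMatrix


def _meta(n, dosages=None, batches=None):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "dosage_percent": dosages if dosages is not None else [100.0] * n,
        "batch": batches if batches is not None else ["b0"] * n,
        "clone": ["c0"] * n,
        "condition": [0] * n,
        "replicate": list(range(n)),
    })


def tmm_oracle(counts: np.ndarray, m_trim=0.30, a_trim=0.05):
    """Independent loop-based trimmed-mean-of-M implementation."""
    lib = counts.sum(axis=0)
    p = counts / lib
    uq = []
    for j in range(counts.shape[1]):
        col = p[:, j][p[:, j] > 0]
        uq.append(np.quantile(col, 0.75))
    uq = np.array(uq)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        ms, as_, ws = [], [], []
        for i in range(counts.shape[0]):
            x, r = counts[i, j], counts[i, ref]
            if x > 0 and r > 0:
                ms.append(np.log2((x / lib[j]) / (r / lib[ref])))
                as_.append(0.5 * np.log2((x / lib[j]) * (r / lib[ref])))
                ws.append((lib[j] - x) / (lib[j] * x) + (lib[ref] - r) / (lib[ref] * r))
        ms, as_, ws = map(np.array, (ms, as_, ws))
        n = len(ms)
        lo_m = np.floor(n * m_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * a_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(ms)
        ra = stats.rankdata(as_)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            logf[j] = np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep])
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        f = tmm_scale_factors(counts)
        assert np.allclose(f, 1.0)

    def test_doubled_library_composition_free(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=500) + 1
        counts = pd.DataFrame({"s0": a, "s1": 2 * a})
        f = tmm_scale_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-12)
        cpm = tmm_normalize(counts, _meta(2))
        assert np.allclose(cpm.values["s0"], cpm.values["s1"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(40, size=(1000, 4)).astype(float) + 1
        up = rng.random(1000) < 0.05
        counts[up, 1] *= 8  # asymmetric differential signal in column B
        df = pd.DataFrame(counts, columns=list("abcd"))
        assert np.allclose(tmm_scale_factors(df), tmm_oracle(counts), atol=1e-6)

    def test_factors_geometric_mean_one(self, small_series):
        _, counts, _, _, cpm = small_series
        assert np.exp(np.mean(np.log(cpm.tmm_factors))) == pytest.approx(1.0, abs=1e-9)

    def test_plain_cpm_columns_sum_to_million(self, small_series):
        _, counts, _, _, _ = small_series
        plain = counts / counts.sum(axis=0) * 1e6
        assert np.allclose(plain.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            tmm_scale_factors(counts)


class TestBatchCorrect:
    def test_single_batch_is_identity(self):
        vals = pd.DataFrame(np.random.default_rng(1).random((5, 4)),
                            columns=[f"s{i}" for i in range(4)])
        m = DoseSeriesMatrix(vals, _meta(4), stage="cpm")
        out = batch_correct(m)
        assert np.allclose(out.values, vals)

    def test_constant_offset_removed_and_grand_mean_kept(self):
        base = np.random.default_rng(2).random((6, 4))
        vals = np.hstack([base, base + 3.0])
        df = pd.DataFrame(vals, columns=[f"s{i}" for i in range(8)])
        meta = _meta(8, batches=["b0"] * 4 + ["b1"] * 4)
        out = batch_correct(DoseSeriesMatrix(df, meta, stage="cpm"))
        b0 = out.values.iloc[:, :4].mean(axis=1)
        b1 = out.values.iloc[:, 4:].mean(axis=1)
        assert np.allclose(b0, b1, atol=1e-9)
        assert np.allclose(out.values.mean(axis=1), df.mean(axis=1), atol=1e-9)

    def test_idempotent(self, small_series):
        _, _, _, _, cpm = small_series
        once = batch_correct(cpm)
        twice = batch_correct(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_confounded_batch_warns(self):
        meta = _meta(4, dosages=[100, 100, 4, 4], batches=["b0", "b0", "b1", "b1"])
        meta["condition"] = [0, 0, 1, 1]
        vals = pd.DataFrame(np.ones((3, 4)), columns=meta["sample_id"])
        with pytest.warns(UserWarning, match="confounded"):
            batch_correct(DoseSeriesMatrix(vals, meta, stage="cpm"))


class TestScaleAndFilter:
    def test_arithmetic_example(self):
        scaled, mask = scale_and_filter([2.0, 4.0, -1.0, 3.0])
        assert np.allclose(scaled, [0.5, 1.0, -0.25, 0.75])
        assert not mask.any()

    def test_single_gross_outlier_masked(self):
        rng = np.random.default_rng(4)
        v = rng.normal(10, 1, size=42)
        v[13] = 25.0
        scaled, mask = scale_and_filter(v)
        assert mask.sum() == 1 and mask[13]
        assert np.isnan(scaled[13])
        # re-running on the retained values leaves unmasked values unchanged
        scaled2, mask2 = scale_and_filter(v[~mask])
        assert not mask2.any()
        assert np.allclose(scaled2, scaled[~mask])

    def test_constant_values_all_one_no_mask(self):
        scaled, mask = scale_and_filter([5.0] * 6)
        assert np.allclose(scaled, 1.0) and not mask.any()

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            scale_and_filter([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            scale_and_filter([1.0, 2.0, 3.0])

    def test_output_magnitude_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(0, 3, size=30)
            scaled, mask = scale_and_filter(v)
            assert np.nanmax(np.abs(scaled)) <= 1.0 + 1e-12


class TestDependentCalls:
    def test_strong_effect_called_null_fdr_controlled(self):
        from tfdose import SimulationConfig, generate_dose_series
        cfg = SimulationConfig(
            n_features_down=30, n_features_up=0, n_features_linear=0,
            n_features_null=2000, nb_dispersion=0.05,
            amplitude_range=(10.0, 10.0), seed=6,
        )
        counts, meta, truth = generate_dose_series(cfg)
        calls = call_dependent_features(tmm_normalize(counts, meta), fdr=0.05)
        called = {c.feature_id for c in calls}
        down_ids = set(truth[truth.true_class == "hill_down"].feature_id)
        assert len(down_ids & called) == 30  # power ~ 1 at 10-fold
        null_ids = set(truth[truth.true_class == "null"].feature_id)
        assert len(null_ids & called) <= 0.05 * 2000 * 2
        for c in calls:
            if c.feature_id in down_ids:
                assert c.direction == "down" and c.effect < 0

    def test_equal_values_not_called(self):
        counts = pd.DataFrame(
            np.vstack([np.full(8, 50), np.random.default_rng(0).poisson(100, 8)]),
            index=["flat", "noisy"], columns=[f"s{i}" for i in range(8)])
        meta = _meta(8, dosages=[100.0] * 4 + [4.0] * 4)
        m = DoseSeriesMatrix(counts.astype(float), meta, stage="cpm")
        calls = call_dependent_features(m)
        assert "flat" not in {c.feature_id for c in calls}

    def test_q_values_match_bruteforce_bh(self):
        """Welch p-values pushed through a hand-coded BH give the same q
        as the implementation reports."""
        from tfdose import SimulationConfig, generate_dose_series
        cfg = SimulationConfig(n_features_down=10, n_features_up=0,
                               n_features_linear=0, n_features_null=90, seed=8)
        counts, meta, _ = generate_dose_series(cfg)
        m = tmm_normalize(counts, meta)
        dos = m.dosages
        logv = np.log2(m.values.to_numpy() + 1.0)
        a, b = logv[:, dos == 4.0], logv[:, dos == 100.0]
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        p = np.nan_to_num(p, nan=1.0)
        # brute-force BH: q_i = min over j with p_j >= p_i of p_j * n / rank_j
        n = len(p)
        order = np.argsort(p)
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        calls = call_dependent_features(m, fdr=0.05)
        ids = list(m.values.index)
        for c in calls:
            assert c.q_value == pytest.approx(q[ids.index(c.feature_id)], abs=1e-12)

    def test_missing_extreme_condition_errors(self):
        counts = pd.DataFrame(np.ones((3, 4)), columns=[f"s{i}" for i in range(4)])
        meta = _meta(4, dosages=[100.0, 4.0, 4.0, 4.0])
        with pytest.raises(ValueError):
            call_dependent_features(DoseSeriesMatrix(counts, meta, stage="cpm"))
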