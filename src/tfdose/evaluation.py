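"""Self-validation benchmarks run against synthetic ground truth.

Each function simulates data under the study conditions (6 dosage levels x
7 replicates, negative-binomial counts at dispersion 0.05, Hill-shaped
responses with 4-8 fold amplitude, a mostly-null feature background for
between-sample normalization), runs the corresponding analysis stage, and
measures how well the known truth is recovered.  These power both the test
suite's acceptance checks and the standalone benchmark script.

Recovery medians for ED50 and the Hill exponent are reported over
good fits (both parameter p-values < 0.05), the same restriction applied
when analysing fitted parameters downstream; all-fit medians are returned
alongside.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_model, bootstrap as bt, dose_response as dr, peaks, preprocess as pp
from .pipeline import RunConfig, run_pipeline
from .simulate import (
    SimulationConfig,
    generate_dose_series,
    generate_regulatory_architecture,
    generate_summits,
)

__all__ = [
    "hill_recovery_benchmark",
    "linear_selection_benchmark",
    "bootstrap_coverage_benchmark",
    "buffering_index_benchmark",
    "abc_round_trip_benchmark",
    "stratification_benchmark",
    "consensus_benchmark",
    "tmm_benchmark",
    "pipeline_reproducibility_benchmark",
]

#: noise/background conditions shared by the fitting benchmarks
_N_NULL_BACKGROUND = 2000


def _benchmark_sim(n_down, n_up, n_linear, seed):
    return SimulationConfig(
        n_features_down=n_down,
        n_features_up=n_up,
        n_features_linear=n_linear,
        n_features_null=_N_NULL_BACKGROUND,
        batch_sd=0.0,
        nb_dispersion=0.05,
        seed=seed,
    )


def _true_cpm(counts, meta):
    """CPM against the generator's true library sizes: the fitting
    benchmarks isolate estimator error from between-sample normalization
    error, which has its own benchmark (tmm_benchmark)."""
    return counts / meta["library_size"].to_numpy() * 1e6


def _fit_all(cfg):
    counts, meta, truth = generate_dose_series(cfg)
    cpm = _true_cpm(counts, meta)
    dos = meta["dosage_percent"].to_numpy(dtype=float)
    fits = {}
    for fid in truth.loc[truth.true_class != "null", "feature_id"]:
        try:
            scaled, _ = pp.scale_and_filter(cpm.loc[fid].to_numpy())
            fits[fid] = dr.fit_dose_response(scaled, dos, feature_id=fid)
        except ValueError:
            continue
    return cpm, truth, fits


def hill_recovery_benchmark(n_features: int = 500, seed: int = 1) -> dict:
    """ED50 / Hill-exponent recovery and Hill-vs-linear selection on
    simulated Hill-shaped features (half down-, half upregulated)."""
    cfg = _benchmark_sim(n_features // 2, n_features - n_features // 2, 0, seed)
    _, truth, fits = _fit_all(cfg)
    rows = []
    for _, t in truth[truth.true_class.str.startswith("hill")].iterrows():
        f = fits.get(t.feature_id)
        if f is None or not f.converged:
            continue
        rows.append(
            {
                "ed50_err": abs(f.ed50 - t.true_ed50),
                "hill_rel_err": abs(f.hill_exponent - t.true_hill) / t.true_hill,
                "delta_aic": f.delta_aic,
                "true_hill": t.true_hill,
                "good": f.good_fit,
            }
        )
    df = pd.DataFrame(rows)
    good = df[df.good]
    steep = df[df.true_hill >= 2]
    return {
        "n_converged": len(df),
        "n_good": len(good),
        "ed50_median_abs_error": float(good.ed50_err.median()),
        "hill_median_rel_error": float(good.hill_rel_err.median()),
        "ed50_median_abs_error_all_fits": float(df.ed50_err.median()),
        "hill_median_rel_error_all_fits": float(df.hill_rel_err.median()),
        "frac_delta_aic_gt2_steep": float((steep.delta_aic > 2).mean()),
        "n_steep": len(steep),
    }


def linear_selection_benchmark(n_features: int = 500, seed: int = 2) -> dict:
    """Fraction of truly linear features that spuriously prefer the Hill
    model (delta AIC > 2)."""
    cfg = _benchmark_sim(0, 0, n_features, seed)
    _, truth, fits = _fit_all(cfg)
    daic = [
        fits[t.feature_id].delta_aic
        for _, t in truth[truth.true_class == "linear"].iterrows()
        if t.feature_id in fits
    ]
    daic = np.asarray(daic)
    return {
        "n": len(daic),
        "frac_spurious_hill": float((daic > 2).mean()),
    }


def bootstrap_coverage_benchmark(
    n_features: int = 300, n_boot: int = 200, seed: int = 3
) -> dict:
    """Empirical coverage of the nominal 95% condition-wise bootstrap CI
    for ED50 on simulated Hill features."""
    cfg = _benchmark_sim(n_features // 2, n_features - n_features // 2, 0, seed)
    counts, meta, truth = generate_dose_series(cfg)
    cpm = _true_cpm(counts, meta)
    dos = meta["dosage_percent"].to_numpy(dtype=float)
    design = {lev: int((dos == lev).sum()) for lev in np.unique(dos)}
    plans = bt.make_resample_plans(design, n_boot=n_boot, seed=seed)
    covered = total = 0
    for _, t in truth[truth.true_class.str.startswith("hill")].iterrows():
        v = cpm.loc[t.feature_id].to_numpy()
        try:
            scaled, _ = pp.scale_and_filter(v)
            f = dr.fit_dose_response(scaled, dos, feature_id=t.feature_id)
        except ValueError:
            continue
        if not f.converged:
            continue
        env = bt.bootstrap_feature(v, dos, plans, full_fit=f, target_id=t.feature_id)
        e = env["ed50"]
        if e.unreliable:
            continue
        total += 1
        covered += bool(e.lower95 <= t.true_ed50 <= e.upper95)
    return {"n": total, "coverage": covered / total if total else np.nan}


def buffering_index_benchmark(n_points: int = 1000, seed: int = 4) -> dict:
    """Agreement of the buffering index with direct evaluation of the
    fitted curve, plus the endpoint identities BI(100)=100, BI(0)=0."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    endpoints_exact = True
    for _ in range(n_points):
        ed50 = rng.uniform(5, 95)
        h = rng.uniform(0.5, 8)
        y0 = rng.uniform(-1, 1)
        y100 = y0 + rng.choice([-1, 1]) * rng.uniform(0.2, 2.0)
        d = rng.uniform(1, 99)
        fit = dr.HillFit(
            feature_id=None, model="hill2", y0=y0, y100=y100, ed50=ed50,
            hill_exponent=h, slope=0, intercept=0, aic_linear=0, aic_hill2=0,
            aic_hill3=0, aic_hill=0, delta_aic=0, p_ed50=0.01, p_hill=0.01,
            converged=True, n_points_used=42, direction="down",
            d_lo=0.0, d_hi=100.0,
        )
        f = fit.predict(np.array([d, 0.0, 100.0]))
        direct = 100.0 - 100.0 * (f[2] - f[0]) / (f[2] - f[1])
        max_dev = max(max_dev, abs(dr.buffering_index(fit, d) - direct))
        endpoints_exact &= dr.buffering_index(fit, 100.0) == 100.0
        endpoints_exact &= abs(dr.buffering_index(fit, 0.0)) < 1e-12
    lin = dr.HillFit(
        feature_id=None, model="linear", y0=0, y100=1, ed50=np.nan,
        hill_exponent=np.nan, slope=1.0, intercept=0.0, aic_linear=0,
        aic_hill2=0, aic_hill3=0, aic_hill=0, delta_aic=0, p_ed50=1,
        p_hill=1, converged=True, n_points_used=42, direction="down",
    )
    return {
        "n": n_points,
        "max_abs_deviation": float(max_dev),
        "endpoints_exact": bool(endpoints_exact),
        "linear_bi50": float(dr.buffering_index(lin, 50.0)),
    }


def abc_round_trip_benchmark(n_genes: int = 300, seed: int = 5) -> dict:
    """Noiseless gene fold-change predictions must reproduce the generator's
    truth exactly; with log-normal gene noise the correlation stays high."""
    cfg = SimulationConfig(seed=seed)
    arch, re_fc, gene_fc = generate_regulatory_architecture(
        cfg, n_genes, res_per_gene=5, gene_noise_sd=0.0)
    links = abc_model.compute_abc_scores(
        arch["res"].assign(chrom=arch["chrom"]),
        arch["genes"].assign(chrom=arch["chrom"]))
    max_err = 0.0
    conds = sorted(c for c in re_fc["condition"].unique() if c != 100.0)
    for cond in conds:
        pred = abc_model.predict_gene_fold_change(links, re_fc, condition=cond)
        obs = gene_fc[gene_fc["condition"] == cond].set_index("gene_id")["fc"]
        p = pred.set_index("gene_id")["predicted_fc"].reindex(obs.index)
        max_err = max(max_err, float((p - obs).abs().max()))

    _, re_fc2, gene_fc2 = generate_regulatory_architecture(
        cfg, n_genes, res_per_gene=5, gene_noise_sd=0.1)
    pl, ol = [], []
    for cond in conds:
        pred = abc_model.predict_gene_fold_change(links, re_fc2, condition=cond)
        obs = gene_fc2[gene_fc2["condition"] == cond].set_index("gene_id")["fc"]
        p = pred.set_index("gene_id")["predicted_fc"].reindex(obs.index)
        pl.append(np.log(p.to_numpy()))
        ol.append(np.log(obs.to_numpy()))
    r = float(np.corrcoef(np.concatenate(pl), np.concatenate(ol))[0, 1])
    return {
        "n_genes": n_genes,
        "n_conditions": len(conds),
        "noiseless_max_abs_error": max_err,
        "noisy_log_fc_pearson_r": r,
    }


def stratification_benchmark(n_genes: int = 300, seed: int = 6) -> dict:
    """Genes spanning the ED50 range: predicted responses stratified by
    fitted gene ED50 must separate the three sensitivity bins."""
    cfg = SimulationConfig(seed=seed)
    arch, re_fc, gene_fc = generate_regulatory_architecture(
        cfg, n_genes, res_per_gene=5, gene_noise_sd=0.1)
    links = abc_model.compute_abc_scores(
        arch["res"].assign(chrom=arch["chrom"]),
        arch["genes"].assign(chrom=arch["chrom"]))
    conds = sorted(re_fc["condition"].unique())
    preds = []
    for cond in conds:
        p = abc_model.predict_gene_fold_change(links, re_fc, condition=cond)
        p.insert(1, "condition", cond)
        preds.append(p.rename(columns={"predicted_fc": "fc"}))
    predicted = pd.concat(preds)[["gene_id", "condition", "fc"]]

    # fit each gene's observed dose-response to get its ED50
    ed50 = {}
    for gid, grp in gene_fc.groupby("gene_id"):
        try:
            f = dr.fit_dose_response(
                np.log2(grp["fc"].to_numpy()), grp["condition"].to_numpy(),
                feature_id=gid)
        except ValueError:
            continue
        if f.converged:
            ed50[gid] = f.ed50
    ed50 = pd.Series(ed50)
    table, tests = abc_model.stratify_predicted_responses(predicted, ed50)
    mid = 51.0  # intermediate dosage
    med = table[table["condition"] == mid].set_index("bin")["median"]
    monotone = bool(med["buffered"] < med["moderate"] < med["high"])
    p = float(tests.loc[tests["condition"] == mid, "kruskal_p"].iloc[0])
    return {
        "n_genes_with_fit": int(len(ed50)),
        "monotone_across_bins": monotone,
        "kruskal_p": p,
    }


def consensus_benchmark(seed: int = 7) -> dict:
    """Consensus peaks vs a brute-force transitive-closure oracle and
    recovery of jittered true peaks; 2-differentiation designs must give
    zero peaks."""

    def bruteforce(positions, window):
        pos = np.asarray(positions)
        n = len(pos)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        order = np.argsort(pos)
        for a in range(n):  # sorted scan is enough for pair linking
            for b in range(a + 1, n):
                i, j = order[a], order[b]
                if pos[j] - pos[i] > window:
                    break
                parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        return sorted(int(np.floor(np.mean(pos[g]) + 0.5)) for g in groups.values())

    rng = np.random.default_rng(seed)
    frames = []
    for r in range(5):
        frames.append(pd.DataFrame({
            "chrom": "chr1",
            "position": rng.integers(0, 2_000_000, 200),
            "replicate": f"rep{r}",
            "differentiation": f"diff{r % 3}",
        }))
    summits = pd.concat(frames, ignore_index=True)
    merged = peaks.merge_summits_within_replicate(summits)
    oracle_ok = True
    for (rep, _), grp in summits.groupby(["replicate", "chrom"]):
        got = sorted(merged[merged.replicate == rep]["position"])
        oracle_ok &= got == bruteforce(grp["position"].to_numpy(), 75)
    supported = peaks.merge_across_replicates(merged, min_support=1)
    oracle_ok &= sorted(supported["position"]) == bruteforce(
        merged["position"].to_numpy(), 150)

    sim_summits, true_peaks = generate_summits(
        n_true_peaks=100, n_replicates=6, n_differentiations=3,
        jitter_sd=20.0, noise_summits_per_replicate=10, seed=seed)
    regions = peaks.call_consensus_peaks(sim_summits)
    recovered = sum(
        ((regions["start"] <= p) & (p < regions["end"])).sum() == 1
        for p in true_peaks["position"])
    noise_regions = len(regions) - sum(
        ((regions["start"] <= p) & (p < regions["end"])).any()
        for p in true_peaks["position"])

    two_diff, _ = generate_summits(50, 6, 2, jitter_sd=20.0,
                                   noise_summits_per_replicate=5, seed=seed)
    n_two = len(peaks.call_consensus_peaks(two_diff))
    return {
        "oracle_identical": bool(oracle_ok),
        "n_true_peaks": 100,
        "recovered_true_peaks": int(recovered),
        "noise_regions": int(noise_regions),
        "two_differentiation_peaks": int(n_two),
    }


def tmm_benchmark(n_matrices: int = 20, seed: int = 8) -> dict:
    """TMM factors vs an independent loop-based oracle; doubled-library
    identity must hold exactly."""
    from scipy import stats as sps

    def oracle(counts, m_trim=0.30, a_trim=0.05):
        lib = counts.sum(axis=0)
        p = counts / lib
        uq = np.array([np.quantile(p[:, j][p[:, j] > 0], 0.75)
                       for j in range(counts.shape[1])])
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
                    ws.append((lib[j] - x) / (lib[j] * x)
                              + (lib[ref] - r) / (lib[ref] * r))
            ms, as_, ws = map(np.array, (ms, as_, ws))
            n = len(ms)
            lo_m = np.floor(n * m_trim) + 1
            lo_a = np.floor(n * a_trim) + 1
            keep = ((sps.rankdata(ms) >= lo_m) & (sps.rankdata(ms) <= n + 1 - lo_m)
                    & (sps.rankdata(as_) >= lo_a) & (sps.rankdata(as_) <= n + 1 - lo_a))
            if keep.any():
                logf[j] = np.sum(ws[keep] * ms[keep]) / np.sum(ws[keep])
        f = 2.0**logf
        return f / np.exp(np.mean(np.log(f)))

    rng = np.random.default_rng(seed)
    max_dev = 0.0
    for _ in range(n_matrices):
        counts = rng.poisson(40, size=(1000, 4)).astype(float) + 1
        up = rng.random(1000) < 0.05
        counts[up, rng.integers(0, 4)] *= 8
        df = pd.DataFrame(counts, columns=list("abcd"))
        dev = np.max(np.abs(pp.tmm_scale_factors(df).to_numpy() - oracle(counts)))
        max_dev = max(max_dev, float(dev))

    a = rng.poisson(50, size=500) + 1
    doubled = pd.DataFrame({"a": a, "b": 2 * a})
    doubled_dev = float(np.max(np.abs(pp.tmm_scale_factors(doubled) - 1.0)))
    return {
        "n_matrices": n_matrices,
        "max_abs_factor_deviation": max_dev,
        "doubled_library_max_deviation": doubled_dev,
    }


def pipeline_reproducibility_benchmark(workdir, seed: int = 9) -> dict:
    """Two full pipeline runs under the same seed must be byte-identical."""
    workdir = Path(workdir)
    cfgs = []
    for name in ("a", "b"):
        cfgs.append(RunConfig(
            sim=SimulationConfig(seed=seed),
            outdir=str(workdir / name),
            seed=seed,
        ))
    reports = [run_pipeline(c) for c in cfgs]
    identical = True
    for p1 in sorted((workdir / "a").iterdir()):
        identical &= filecmp.cmp(p1, workdir / "b" / p1.name, shallow=False)
    return {
        "byte_identical": bool(identical),
        "features_called": reports[0]["counts"].get("features_called", 0),
        "fits_converged": reports[0]["counts"].get("fits_converged", 0),
        "consensus_peaks": reports[0]["counts"].get("consensus_peaks", 0),
        "genes_predicted": reports[0]["counts"].get("genes_predicted", 0),
        "sensitivity_classes": reports[0]["counts"].get("sensitivity_classes", {}),
    }
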