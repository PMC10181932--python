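"""End-to-end orchestration: simulate -> preprocess -> fit -> bootstrap ->
ABC prediction -> consensus peaks, with per-stage TSV/BED artifacts.

Every artifact carries the package version, seed and a configuration hash
in its header; runs with the same configuration and seed are
byte-identical.  Stage failures abort the run with the failing stage named
and a FAILED marker left next to the partial outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_model, bootstrap as bt, dose_response as dr, peaks, preprocess as pp
from .io import config_hash, write_tsv
from .simulate import (
    SimulationConfig,
    generate_dose_series,
    generate_regulatory_architecture,
    generate_summits,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tfdose")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data pipeline run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "tfdose_run"
    seed: int = 1
    fdr: float = 0.05
    n_boot: int = 200
    bootstrap_max_features: int = 20  # cap on per-feature bootstraps, for runtime
    thresholds: tuple[float, float] = (30.0, 40.0)
    n_genes: int = 300
    res_per_gene: int = 5
    gene_noise_sd: float = 0.1
    n_true_peaks: int = 200
    n_summit_replicates: int = 6
    n_differentiations: int = 3
    run_simulate: bool = True
    run_preprocess: bool = True
    run_fit: bool = True
    run_bootstrap: bool = True
    run_abc: bool = True
    run_consensus: bool = True

    def validate(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("classification thresholds must be strictly increasing")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        self.sim.validate()


def _fits_frame(fits, calls_by_id, thresholds):
    rows = []
    for f in fits:
        cls = dr.classify_sensitivity(f, thresholds).sensitivity_class
        bi50 = np.nan
        if f.converged:
            try:
                bi50 = dr.buffering_index(f, 50.0)
            except ValueError:
                pass
        rows.append(
            {
                "feature_id": f.feature_id,
                "model": f.model,
                "y0": f.y0,
                "y100": f.y100,
                "ed50": f.ed50,
                "hill_exponent": f.hill_exponent,
                "aic_linear": f.aic_linear,
                "aic_hill2": f.aic_hill2,
                "aic_hill3": f.aic_hill3,
                "delta_aic": f.delta_aic,
                "p_ed50": f.p_ed50,
                "p_hill": f.p_hill,
                "converged": f.converged,
                "direction": calls_by_id.get(f.feature_id, f.direction),
                "sensitivity_class": cls,
                "buffering_index_50": bi50,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # outdir is not part of the run's semantics; identical runs into
    # different directories hash identically
    cfg = {"run": {k: v for k, v in asdict(config).items() if k != "outdir"},
           "seed": config.seed}
    chash = config_hash(cfg)
    report: dict = {"seed": config.seed, "config_hash": chash, "outputs": [], "counts": {},
                    "warnings": 0}

    def emit(df, name, stage, index=False):
        path = outdir / name
        write_tsv(df, path, stage=stage, seed=config.seed, cfg_hash=chash, index=index)
        report["outputs"].append(str(path))

    if not config.run_simulate:
        report["counts"]["stages_completed"] = "none"
        return report

    stage = "simulate"
    try:
        config.sim.seed = config.seed
        counts, metadata, truth = generate_dose_series(config.sim)
        emit(counts, "counts.tsv", "raw", index=True)
        emit(metadata, "metadata.tsv", "metadata")
        emit(truth, "truth.tsv", "truth")
        report["counts"]["features_simulated"] = len(counts)

        matrix = None
        calls = []
        if config.run_preprocess:
            stage = "preprocess"
            cpm = pp.tmm_normalize(counts, metadata)
            matrix = pp.batch_correct(cpm)
            calls = pp.call_dependent_features(cpm, fdr=config.fdr)
            calls_df = pd.DataFrame(
                [{"feature_id": c.feature_id, "direction": c.direction,
                  "effect": c.effect, "q_value": c.q_value} for c in calls]
            )
            emit(calls_df, "dependent_features.tsv", "calls")
            report["counts"]["features_called"] = len(calls)

        fits = []
        if config.run_fit and matrix is not None:
            stage = "fit"
            dosages = matrix.dosages
            call_dir = {c.feature_id: c.direction for c in calls}
            for c in calls:
                vals = matrix.values.loc[c.feature_id].to_numpy(dtype=float)
                try:
                    scaled, _ = pp.scale_and_filter(vals)
                    fits.append(dr.fit_dose_response(scaled, dosages,
                                                     feature_id=c.feature_id))
                except ValueError:
                    log.warning("feature %s not fittable", c.feature_id)
                    report["warnings"] += 1
            fits_df = _fits_frame(fits, call_dir, config.thresholds)
            emit(fits_df, "fits.tsv", "fits")
            n_conv = int(sum(f.converged for f in fits))
            tallies = fits_df.loc[fits_df["converged"], "sensitivity_class"].value_counts()
            report["counts"]["fits_converged"] = n_conv
            report["counts"]["sensitivity_classes"] = {k: int(v) for k, v in tallies.items()}
            report["warnings"] += int(np.sum(fits_df["ed50"] > 100))

        if config.run_bootstrap and fits:
            stage = "bootstrap"
            design = (
                metadata.groupby("dosage_percent")["sample_id"].count().to_dict()
            )
            plans = bt.make_resample_plans(design, n_boot=config.n_boot,
                                           seed=config.seed)
            env_rows = []
            for f in fits[: config.bootstrap_max_features]:
                if not f.converged:
                    continue
                vals = matrix.values.loc[f.feature_id].to_numpy(dtype=float)
                envs = bt.bootstrap_feature(vals, matrix.dosages, plans,
                                            full_fit=f, target_id=f.feature_id)
                for e in envs.values():
                    env_rows.append(
                        {
                            "target_id": e.target_id,
                            "statistic": e.statistic,
                            "estimate": e.point_estimate,
                            "lower95": e.lower95,
                            "upper95": e.upper95,
                            "n_converged": e.n_converged,
                            "unreliable": e.unreliable,
                        }
                    )
            emit(pd.DataFrame(env_rows), "bootstrap_ci.tsv", "bootstrap")
            report["counts"]["features_bootstrapped"] = len(env_rows) // 2

        if config.run_abc:
            stage = "abc"
            arch, re_fc, gene_fc = generate_regulatory_architecture(
                config.sim, config.n_genes, config.res_per_gene,
                gene_noise_sd=config.gene_noise_sd,
            )
            res_tbl = arch["res"].assign(chrom=arch["chrom"])
            genes_tbl = arch["genes"].assign(chrom=arch["chrom"])
            links = abc_model.compute_abc_scores(res_tbl, genes_tbl)
            preds = []
            for cond in sorted(re_fc["condition"].unique()):
                p = abc_model.predict_gene_fold_change(links, re_fc, condition=cond)
                p.insert(1, "condition", cond)
                preds.append(p)
            preds_df = pd.concat(preds, ignore_index=True)
            emit(links, "abc_links.tsv", "abc")
            emit(preds_df, "gene_predictions.tsv", "abc")
            emit(gene_fc, "gene_observed_fc.tsv", "abc")
            report["counts"]["genes_predicted"] = int(preds_df["gene_id"].nunique())

        if config.run_consensus:
            stage = "consensus"
            summits, true_peaks = generate_summits(
                config.n_true_peaks, config.n_summit_replicates,
                config.n_differentiations, seed=config.seed,
            )
            consensus = peaks.call_consensus_peaks(summits)
            emit(consensus, "consensus_peaks.bed", "consensus")
            report["counts"]["consensus_peaks"] = len(consensus)
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        log.error("pipeline failed at stage %s", stage)
        raise

    report["counts"]["stages_completed"] = stage
    return report
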