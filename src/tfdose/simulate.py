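"""Synthetic titration datasets with known ground truth.

Emulates a degron-style TF dosage series: a feature (regulatory element or
gene) by sample count matrix across six graded TF dosages with ~7 biological
replicates per dosage, multiplicative per-batch effects and negative-binomial
counting noise.  True per-feature responses are Hill-shaped (in either
direction), linear, or null, and a companion regulatory architecture ties
gene responses to ABC-weighted combinations of regulatory-element responses.

All generators are fully seeded: the same configuration and seed give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "hill_mean",
    "generate_dose_series",
    "generate_regulatory_architecture",
    "generate_summits",
]

#: length of the single synthetic contig, bp
CONTIG_NAME = "chrS"
CONTIG_LENGTH = 100_000_000


@dataclass
class SimulationConfig:
    """Conditions of a simulated titration experiment.

    Dosage levels are percent of the unperturbed TF level, strictly
    decreasing from 100 and reaching a near-full depletion (<= 5%).
    ``batch_sd`` is the log2-scale standard deviation of multiplicative
    per-(batch, feature) effects; ``nb_dispersion`` is the negative-binomial
    dispersion alpha (variance = mu + alpha * mu^2).
    """

    n_features_down: int = 150
    n_features_up: int = 150
    n_features_linear: int = 100
    n_features_null: int = 1600
    dosage_levels: tuple[float, ...] = (100.0, 72.0, 51.0, 36.0, 18.0, 4.0)
    n_replicates_per_level: int = 7
    n_batches: int = 4
    batch_sd: float = 0.1
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (8_000_000.0, 12_000_000.0)
    ed50_range: tuple[float, float] = (10.0, 90.0)
    hill_range: tuple[float, float] = (1.0, 6.0)
    amplitude_range: tuple[float, float] = (4.0, 8.0)
    baseline_range: tuple[float, float] = (10.0, 200.0)
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_features_down,
            self.n_features_up,
            self.n_features_linear,
            self.n_features_null,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("at least one feature is required")
        if self.n_replicates_per_level < 1:
            raise ValueError("need at least one replicate per dosage level")
        lv = list(self.dosage_levels)
        if lv[0] != 100 or any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("dosage_levels must be strictly decreasing from 100")
        if min(lv) > 5:
            raise ValueError("dosage_levels must include a near-full depletion (<= 5)")
        lo, hi = self.ed50_range
        if not (0 < lo <= hi < 100):
            raise ValueError("ed50_range must lie strictly inside (0, 100)")
        if self.hill_range[0] <= 0:
            raise ValueError("hill_range must be positive")
        if self.amplitude_range[0] < 1:
            raise ValueError("amplitudes are fold-changes >= 1")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")

    def to_dict(self) -> dict:
        return asdict(self)


def hill_mean(d, y0, y100, ed50, h):
    """Hill response: value ``y0`` at 0% dosage rising (or falling) to
    ``y100`` at 100% with half-transition at ``ed50`` and steepness ``h``."""
    d = np.asarray(d, dtype=float)
    frac = np.zeros_like(d)
    pos = d > 0
    frac[pos] = d[pos] ** h / (ed50**h + d[pos] ** h)
    return y0 + (y100 - y0) * frac


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and variance mu + alpha*mu^2
    via the gamma-Poisson mixture; alpha == 0 degenerates to Poisson."""
    mu = np.clip(mu, 1e-12, None)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _draw_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    classes = (
        ["hill_down"] * cfg.n_features_down
        + ["hill_up"] * cfg.n_features_up
        + ["linear"] * cfg.n_features_linear
        + ["null"] * cfg.n_features_null
    )
    for i, cls in enumerate(classes):
        baseline = np.exp(rng.uniform(*np.log(cfg.baseline_range)))
        amp = rng.uniform(*cfg.amplitude_range)
        ed50 = hill = np.nan
        if cls == "hill_down":
            # accessibility falls when the TF is depleted: mean rises with dosage
            y100, y0 = baseline, baseline / amp
            ed50 = rng.uniform(*cfg.ed50_range)
            hill = rng.uniform(*cfg.hill_range)
        elif cls == "hill_up":
            y0, y100 = baseline, baseline / amp
            ed50 = rng.uniform(*cfg.ed50_range)
            hill = rng.uniform(*cfg.hill_range)
        elif cls == "linear":
            if rng.random() < 0.5:
                y100, y0 = baseline, baseline / amp
            else:
                y0, y100 = baseline, baseline / amp
        else:
            y0 = y100 = baseline
        rows.append(
            {
                "feature_id": f"f{i:05d}",
                "true_class": cls,
                "true_ed50": ed50,
                "true_hill": hill,
                "true_y0": y0,
                "true_y100": y100,
            }
        )
    return pd.DataFrame(rows)


def _true_mean(truth_row: pd.Series, dosage: np.ndarray) -> np.ndarray:
    cls = truth_row["true_class"]
    y0, y100 = truth_row["true_y0"], truth_row["true_y100"]
    if cls in ("hill_down", "hill_up"):
        return hill_mean(dosage, y0, y100, truth_row["true_ed50"], truth_row["true_hill"])
    # linear and null are both affine in dosage (null has y0 == y100)
    return y0 + (y100 - y0) * np.asarray(dosage, dtype=float) / 100.0


def generate_dose_series(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a raw count matrix for a full titration series.

    Returns
    -------
    counts : DataFrame, features x samples, integer counts
    metadata : DataFrame with sample_id, dosage_percent, batch, clone,
        condition (index into the dosage ladder), replicate and the true
        library_size used for count scaling
    truth : DataFrame, one row per feature with the generating parameters
        (per-batch multipliers are appended as ``batch_<b>`` columns)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    n_feat = len(truth)

    meta_rows = []
    for ci, dose in enumerate(config.dosage_levels):
        for r in range(config.n_replicates_per_level):
            meta_rows.append(
                {
                    "sample_id": f"d{dose:g}_r{r}",
                    "dosage_percent": float(dose),
                    # replicates are biological differentiations shared across
                    # the dosage ladder, so batch follows the replicate index
                    "batch": f"b{r % config.n_batches}",
                    "clone": f"c{r % 2}",
                    "condition": ci,
                    "replicate": r,
                }
            )
    metadata = pd.DataFrame(meta_rows)

    batch_ids = sorted(metadata["batch"].unique())
    batch_mult = 2.0 ** rng.normal(0.0, config.batch_sd, size=(n_feat, len(batch_ids)))
    for j, b in enumerate(batch_ids):
        truth[f"batch_{b}"] = batch_mult[:, j]

    lib_sizes = rng.uniform(*config.library_size_range, size=len(metadata))
    metadata["library_size"] = lib_sizes
    dosages = metadata["dosage_percent"].to_numpy()
    batch_idx = metadata["batch"].map({b: j for j, b in enumerate(batch_ids)}).to_numpy()

    mean_cpm = np.vstack([_true_mean(row, dosages) for _, row in truth.iterrows()])
    mean_cpm = mean_cpm * batch_mult[:, batch_idx]
    mu = mean_cpm * (lib_sizes / 1e6)[None, :]
    counts = _nb_counts(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(
        counts, index=truth["feature_id"].to_numpy(), columns=metadata["sample_id"].to_numpy()
    )
    counts_df.index.name = "feature_id"
    return counts_df, metadata, truth


# ---------------------------------------------------------------------------
# regulatory architecture: genes whose responses are ABC-weighted RE responses


def generate_regulatory_architecture(
    config: SimulationConfig,
    n_genes: int,
    res_per_gene: int,
    gene_noise_sd: float = 0.1,
    contact_exponent: float = 0.7,
):
    """Simulate an RE -> gene architecture on a single synthetic contig.

    Each gene gets a TSS and ``res_per_gene`` regulatory elements within
    +/- 2 Mb; every RE responds with a Hill curve whose midpoint is drawn
    near a per-gene base ED50 so genes have coherent sensitivities.  The
    true gene fold change at each dosage is the ABC-weighted mean of its
    REs' fold changes times exp(N(0, gene_noise_sd)) noise.

    Returns (architecture, re_fc, gene_fc):
    architecture : dict with ``genes`` (gene_id, tss), ``res`` (re_id, gene_id,
        position, baseline_atac, baseline_k27ac, true_ed50, true_hill,
        true_amplitude) DataFrames and ``gene_noise_sd``
    re_fc : DataFrame (re_id, condition=dosage percent, fc) long format,
        fold change vs 100% dosage
    gene_fc : same for genes
    """
    config.validate()
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if res_per_gene < 1:
        raise ValueError("res_per_gene must be >= 1")
    rng = np.random.default_rng(config.seed + 1)

    margin = 2_100_000
    tss = np.sort(rng.integers(margin, CONTIG_LENGTH - margin, size=n_genes))
    genes = pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(n_genes)], "tss": tss})

    re_rows = []
    for gi in range(n_genes):
        base_ed50 = rng.uniform(*config.ed50_range)
        for k in range(res_per_gene):
            # keep REs outside the 1 kb promoter-exclusion zone
            offset = rng.uniform(2_000, 2_000_000) * rng.choice([-1, 1])
            ed50 = float(np.clip(base_ed50 + rng.normal(0, 3.0), 1.0, 99.0))
            re_rows.append(
                {
                    "re_id": f"re{gi:04d}_{k}",
                    "gene_id": genes["gene_id"].iloc[gi],
                    "position": int(tss[gi] + offset),
                    "baseline_atac": float(np.exp(rng.uniform(np.log(5), np.log(200)))),
                    "baseline_k27ac": float(np.exp(rng.uniform(np.log(5), np.log(200)))),
                    "true_ed50": ed50,
                    "true_hill": float(rng.uniform(*config.hill_range)),
                    "true_amplitude": float(rng.uniform(*config.amplitude_range)),
                }
            )
    res = pd.DataFrame(re_rows)

    dosages = np.asarray(config.dosage_levels, dtype=float)
    # RE fold change vs the 100% condition; amplitude-fold drop at full depletion
    fc_rows = []
    re_fc_matrix = np.empty((len(res), len(dosages)))
    for i, row in res.iterrows():
        y100, y0 = 1.0, 1.0 / row["true_amplitude"]
        m = hill_mean(dosages, y0, y100, row["true_ed50"], row["true_hill"])
        fc = m / m[dosages == 100.0][0]
        re_fc_matrix[i] = fc
        for d, f in zip(dosages, fc):
            fc_rows.append({"re_id": row["re_id"], "condition": d, "fc": f})
    re_fc = pd.DataFrame(fc_rows)

    # gene fold change = ABC-weighted mean over ALL REs within the 5 Mb
    # window of the gene's TSS (promoter zone excluded), matching the ABC
    # linking rule; weights dist^-gamma * sqrt(atac * k27ac), normalized.
    positions = res["position"].to_numpy(dtype=float)
    activity = np.sqrt(res["baseline_atac"].to_numpy() * res["baseline_k27ac"].to_numpy())
    gene_rows = []
    for gi, gid in enumerate(genes["gene_id"]):
        dist = np.abs(positions - tss[gi])
        sel = (dist > 1_000) & (dist <= 5_000_000)
        raw = dist[sel] ** (-contact_exponent) * activity[sel]
        w = raw / raw.sum()
        fc = w @ re_fc_matrix[sel]
        if gene_noise_sd > 0:
            fc = fc * np.exp(rng.normal(0.0, gene_noise_sd, size=fc.shape))
            fc[dosages == 100.0] = 1.0  # fold change vs itself is exact
        for d, f in zip(dosages, fc):
            gene_rows.append({"gene_id": gid, "condition": d, "fc": float(f)})
    gene_fc = pd.DataFrame(gene_rows)

    architecture = {
        "genes": genes,
        "res": res,
        "gene_noise_sd": gene_noise_sd,
        "contact_exponent": contact_exponent,
        "chrom": CONTIG_NAME,
    }
    return architecture, re_fc, gene_fc


# ---------------------------------------------------------------------------
# replicate summit calls for the consensus-peak stage


def generate_summits(
    n_true_peaks: int,
    n_replicates: int,
    n_differentiations: int,
    jitter_sd: float = 20.0,
    noise_summits_per_replicate: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-replicate summit calls around shared true peaks.

    Each true peak appears in every replicate at its position plus rounded
    N(0, jitter_sd) jitter; noise summits are uniform on the contig.
    Replicates are assigned to differentiations round-robin.

    Returns (summits, true_peaks): summits has chrom, position, replicate,
    differentiation; true_peaks has chrom, position.
    """
    if n_true_peaks < 0 or n_replicates < 1:
        raise ValueError("need >= 0 peaks and >= 1 replicate")
    if n_differentiations < 1:
        raise ValueError("need >= 1 differentiation")
    rng = np.random.default_rng(seed)
    # spread true peaks with >= 2 kb spacing so they never merge with each other
    spacing = CONTIG_LENGTH // max(n_true_peaks + 1, 2)
    base = np.arange(1, n_true_peaks + 1) * spacing
    positions = base + rng.integers(0, max(spacing - 2000, 1), size=n_true_peaks)
    true_peaks = pd.DataFrame({"chrom": CONTIG_NAME, "position": positions})

    rows = []
    for r in range(n_replicates):
        diff = f"diff{r % n_differentiations}"
        rep = f"rep{r}"
        jitter = np.round(rng.normal(0, jitter_sd, size=n_true_peaks)).astype(int)
        for p in np.maximum(positions + jitter, 0):
            rows.append({"chrom": CONTIG_NAME, "position": int(p), "replicate": rep,
                         "differentiation": diff})
        for p in rng.integers(0, CONTIG_LENGTH, size=noise_summits_per_replicate):
            rows.append({"chrom": CONTIG_NAME, "position": int(p), "replicate": rep,
                         "differentiation": diff})
    summits = pd.DataFrame(rows, columns=["chrom", "position", "replicate", "differentiation"])
    return summits, true_peaks
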