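"""Normalization and filtering ahead of dose-response fitting.

Counts are TMM-normalized to CPM, corrected for differentiation batch by
per-feature linear regression, scaled to [-1, 1] by the maximum absolute
value, and outlier samples (|z| > 3) are masked.  TF-dependent features are
flagged with a two-group Welch test between the extreme dosages with
Benjamini-Hochberg control — a simple, documented stand-in for a
count-model differential test, whose only contract here is FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DoseSeriesMatrix",
    "DependentFeatureCall",
    "tmm_scale_factors",
    "tmm_normalize",
    "batch_correct",
    "scale_and_filter",
    "call_dependent_features",
]


@dataclass
class DoseSeriesMatrix:
    """Feature x sample abundances tied to per-sample titration metadata.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample; ``metadata`` has one row per sample (sample_id, dosage_percent,
    batch, clone, condition, replicate); ``stage`` tracks processing state.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    stage: str = "raw"
    tmm_factors: pd.Series | None = None

    def __post_init__(self):
        meta_ids = list(self.metadata["sample_id"])
        if list(self.values.columns) != meta_ids:
            raise ValueError("matrix columns must match metadata sample_ids in order")
        if self.stage in ("raw", "cpm") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.stage} values must be non-negative")

    @property
    def dosages(self) -> np.ndarray:
        return self.metadata["dosage_percent"].to_numpy(dtype=float)


@dataclass
class DependentFeatureCall:
    feature_id: str
    direction: str  # "down": lower at depletion; "up": higher at depletion
    effect: float  # log2 fold change, depleted vs 100% dosage
    q_value: float


def tmm_scale_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors.

    The reference is the sample whose upper quartile (of library-normalized
    counts) is closest to the mean upper quartile.  For each sample, log
    ratios M and average abundances A versus the reference are computed over
    features nonzero in both; the top/bottom ``m_trim`` of M and ``a_trim``
    of A are discarded and the remaining M are averaged with edgeR-style
    precision weights.  Factors are renormalized to geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    for j, s in enumerate(counts.columns):
        if lib[j] == 0:
            raise ValueError(f"sample {s!r} has zero total count")
    p = x / lib
    uq = np.array([np.quantile(p[:, j][p[:, j] > 0], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(x.shape[1])
    xr, nr = x[:, ref], lib[ref]
    for j in range(x.shape[1]):
        if j == ref:
            continue
        xs, ns = x[:, j], lib[j]
        ok = (xs > 0) & (xr > 0)
        m = np.log2((xs[ok] / ns) / (xr[ok] / nr))
        a = 0.5 * np.log2((xs[ok] / ns) * (xr[ok] / nr))
        w = (ns - xs[ok]) / (ns * xs[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        n = m.size
        if n == 0:
            continue
        # rank-based double trim, as in edgeR
        lo_m, hi_m = np.floor(n * m_trim) + 1, n + 1 - (np.floor(n * m_trim) + 1)
        lo_a, hi_a = np.floor(n * a_trim) + 1, n + 1 - (np.floor(n * a_trim) + 1)
        rm = stats.rankdata(m, method="average")
        ra = stats.rankdata(a, method="average")
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0 or not np.isfinite(m[keep]).all():
            continue
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])

    factors = 2.0**log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_normalize(counts: pd.DataFrame, metadata: pd.DataFrame) -> DoseSeriesMatrix:
    """TMM-normalized CPM: count / (library size x factor) x 1e6."""
    if counts.shape[1] < 2:
        raise ValueError("TMM normalization needs at least two samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    factors = tmm_scale_factors(counts)
    lib = counts.sum(axis=0)
    cpm = counts / (lib * factors) * 1e6
    return DoseSeriesMatrix(values=cpm, metadata=metadata, stage="cpm", tmm_factors=factors)


def batch_correct(matrix: DoseSeriesMatrix) -> DoseSeriesMatrix:
    """Remove additive per-batch offsets per feature by least squares.

    Fitting abundance ~ batch indicators and keeping residuals + the
    feature grand mean equalizes per-batch means exactly (the closed form
    of a one-factor regression).  Warns when a batch is perfectly
    confounded with a dosage condition, since correction may then absorb
    real signal.
    """
    meta = matrix.metadata
    batches = meta["batch"].to_numpy()
    for cond, grp in meta.groupby("condition"):
        b = set(grp["batch"])
        if len(b) == 1 and set(meta.loc[meta["batch"].isin(b), "condition"]) == {cond}:
            warnings.warn(
                f"batch {b.pop()!r} is confounded with condition {cond}; "
                "batch correction may absorb dosage signal"
            )
    vals = matrix.values.to_numpy(dtype=float)
    corrected = vals.copy()
    grand = vals.mean(axis=1, keepdims=True)
    for b in np.unique(batches):
        sel = batches == b
        corrected[:, sel] -= vals[:, sel].mean(axis=1, keepdims=True)
    corrected += grand
    out = pd.DataFrame(corrected, index=matrix.values.index, columns=matrix.values.columns)
    return DoseSeriesMatrix(out, meta, stage="batch_corrected", tmm_factors=matrix.tmm_factors)


def scale_and_filter(values: np.ndarray, z_threshold: float = 3.0):
    """Scale one feature's corrected abundances to [-1, 1], masking outliers.

    Outliers are samples with |value - mean| / sd > ``z_threshold``,
    computed on the corrected (pre-scaling) values across all samples.
    Retained values are divided by their maximum absolute value, so output
    magnitudes are <= 1; masked positions are NaN.

    Returns (scaled, mask) where ``mask`` is True for removed samples.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 non-missing values")
    mask = ~finite
    vv = v[finite]
    sd = vv.std(ddof=1)
    if sd > 0:
        z = np.abs(v - vv.mean()) / sd
        mask |= finite & (z > z_threshold)
    retained = v[~mask]
    denom = np.max(np.abs(retained))
    if denom == 0:
        raise ValueError("degenerate feature: all retained values are zero")
    scaled = np.where(mask, np.nan, v / denom)
    return scaled, mask


def call_dependent_features(
    matrix: DoseSeriesMatrix,
    fdr: float = 0.05,
    log_offset: float = 1.0,
) -> list[DependentFeatureCall]:
    """Flag features responding to full depletion (lowest vs 100% dosage).

    Welch's t-test on log2(CPM + offset) between the highest- and
    lowest-dosage conditions, Benjamini-Hochberg corrected across features;
    calls are features with q < ``fdr``.  Features with zero variance in
    both groups get p = 1 when group means agree (and p = 0 otherwise).
    """
    dos = matrix.dosages
    hi, lo = dos.max(), dos.min()
    hi_idx, lo_idx = dos == hi, dos == lo
    if hi_idx.sum() < 2 or lo_idx.sum() < 2:
        raise ValueError("need >= 2 replicates in both extreme dosage conditions")

    logv = np.log2(matrix.values.to_numpy(dtype=float) + log_offset)
    a, b = logv[:, lo_idx], logv[:, hi_idx]  # depleted, unperturbed
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    effect = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    pvals = np.where(zero_var, np.where(effect == 0, 1.0, 0.0), pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    calls = []
    for fid, eff, q in zip(matrix.values.index, effect, qvals):
        if q < fdr:
            calls.append(
                DependentFeatureCall(
                    feature_id=str(fid),
                    direction="down" if eff < 0 else "up",
                    effect=float(eff),
                    q_value=float(q),
                )
            )
    return calls
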