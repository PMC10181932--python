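"""Condition-wise bootstrap for ED50 / Hill-exponent uncertainty.

Parametric standard errors from nonlinear least squares are unstable for
dose-response parameters, so uncertainty is quantified by resampling
replicates with replacement *within* each dosage condition (keeping the
design balanced), refitting the Hill model to each of the (default 200)
resampled datasets, and summarizing the refit parameters into percentile
95% confidence intervals.  Group-level intervals are built by computing the
group statistic (median) across members separately at each bootstrap index,
never by pooling member percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_response import HillFit, fit_dose_response
from .preprocess import scale_and_filter

__all__ = [
    "ResamplePlan",
    "BootstrapEnvelope",
    "make_resample_plans",
    "bootstrap_feature",
    "bootstrap_group_statistic",
]

N_BOOT_DEFAULT = 200


@dataclass
class ResamplePlan:
    """Replicate indices (with replacement) per condition, one bootstrap."""

    bootstrap_index: int
    indices: dict  # condition key -> int array, length = replicate count


@dataclass
class BootstrapEnvelope:
    target_id: str
    statistic: str  # "ed50" or "hill_exponent"
    point_estimate: float
    boot_values: np.ndarray  # length n_boot, NaN where the refit failed
    lower95: float
    upper95: float
    n_converged: int
    unreliable: bool  # > 50% of refits failed to converge

    @property
    def n_boot(self) -> int:
        return len(self.boot_values)


def make_resample_plans(design: dict, n_boot: int = N_BOOT_DEFAULT, seed: int = 0):
    """Seeded within-condition resampling plans.

    ``design`` maps condition key -> replicate count.  Sampling is with
    replacement, independent across conditions and bootstraps; the plan list
    depends only on (seed, design, n_boot).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    for cond, n in design.items():
        if n < 1:
            raise ValueError(f"condition {cond!r} has no replicates")
    rng = np.random.default_rng(seed)
    conds = list(design)
    plans = []
    for b in range(n_boot):
        idx = {c: rng.integers(0, design[c], size=design[c]) for c in conds}
        plans.append(ResamplePlan(bootstrap_index=b, indices=idx))
    return plans


def _condition_index(dosages: np.ndarray) -> dict:
    """Sample positions per condition, keyed by dosage level."""
    return {lev: np.flatnonzero(dosages == lev) for lev in np.unique(dosages)}


def bootstrap_feature(
    values,
    dosages,
    plans,
    full_fit: HillFit | None = None,
    target_id: str | None = None,
    refilter_outliers: bool = True,
    starts=None,
) -> dict:
    """Refit one feature under every resampling plan.

    ``values`` are batch-corrected (pre-scaling) abundances; each bootstrap
    dataset is resampled first, then outlier-masked (|z| > 3) and rescaled,
    mirroring the full-data path (set ``refilter_outliers=False`` to skip
    the per-bootstrap mask).  Refits keep the full-data hill2/hill3 choice
    so the parameter being resampled is defined identically throughout.

    Returns {"ed50": BootstrapEnvelope, "hill_exponent": BootstrapEnvelope}.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if full_fit is None:
        scaled, _ = scale_and_filter(v) if refilter_outliers else (v, None)
        full_fit = fit_dose_response(scaled, d, feature_id=target_id)
    variant = full_fit.model if full_fit.model in ("hill2", "hill3") else "hill2"
    # refits start from the full-data estimate: resampled datasets are
    # perturbations of the original, so its basin is the right one
    if starts is None:
        starts = (full_fit.ed50,) if np.isfinite(full_fit.ed50) else (20.0, 50.0, 80.0)

    cond_pos = _condition_index(d)
    boot_e = np.full(len(plans), np.nan)
    boot_h = np.full(len(plans), np.nan)
    for i, plan in enumerate(plans):
        take = np.concatenate([cond_pos[c][plan.indices[c] % len(cond_pos[c])]
                               for c in cond_pos])
        bv, bd = v[take], d[take]
        try:
            if refilter_outliers:
                bv, _ = scale_and_filter(bv)
            fit = fit_dose_response(bv, bd, variant=variant, starts=starts)
        except ValueError:
            continue
        if fit.converged:
            boot_e[i] = fit.ed50
            boot_h[i] = fit.hill_exponent

    out = {}
    for name, boots, point in (
        ("ed50", boot_e, full_fit.ed50),
        ("hill_exponent", boot_h, full_fit.hill_exponent),
    ):
        okb = boots[np.isfinite(boots)]
        n_conv = okb.size
        if n_conv:
            lo, hi = np.percentile(okb, [2.5, 97.5])
        else:
            lo = hi = np.nan
        out[name] = BootstrapEnvelope(
            target_id=target_id or (full_fit.feature_id or "feature"),
            statistic=name,
            point_estimate=float(point),
            boot_values=boots,
            lower95=float(lo),
            upper95=float(hi),
            n_converged=n_conv,
            unreliable=n_conv < 0.5 * len(plans),
        )
    return out


def bootstrap_group_statistic(
    envelopes, statistic=np.nanmedian, group_id: str = "group"
) -> BootstrapEnvelope:
    """Group envelope from member envelopes sharing the same plans.

    Bootstrap value b of the group is the statistic (default median, NaN
    members skipped) across members' values at index b, preserving the
    within-bootstrap pairing of refits.
    """
    envelopes = list(envelopes)
    if not envelopes:
        raise ValueError("empty group")
    n_boot = envelopes[0].n_boot
    stat_name = envelopes[0].statistic
    for e in envelopes:
        if e.n_boot != n_boot:
            raise ValueError("members have mismatched n_boot")
    mat = np.vstack([e.boot_values for e in envelopes])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        group_boots = statistic(mat, axis=0)
    okb = group_boots[np.isfinite(group_boots)]
    lo, hi = (np.percentile(okb, [2.5, 97.5]) if okb.size else (np.nan, np.nan))
    point = float(statistic(np.asarray([e.point_estimate for e in envelopes])[None, :], axis=1)[0])
    return BootstrapEnvelope(
        target_id=group_id,
        statistic=stat_name,
        point_estimate=point,
        boot_values=group_boots,
        lower95=float(lo),
        upper95=float(hi),
        n_converged=int(okb.size),
        unreliable=okb.size < 0.5 * n_boot,
    )
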