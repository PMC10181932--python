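"""Per-feature dose-response modelling of a TF titration series.

Each feature's scaled abundances are fitted as a function of TF dosage
(percent of the unperturbed level) with

* a linear model ``y = a*d + b``,
* a two-parameter Hill equation whose minimum and maximum are fixed to the
  condition means at full and no depletion (free: ED50, Hill exponent h),
  and
* a three-parameter variant with the no-depletion maximum free.

"Fixed minimum and maximum" means the fitted curve passes through those
values at the anchor dosages: with u(d) = d^h / (ED50^h + d^h),

    y(d) = y_min + (y_max - y_min) * (u(d) - u(d_lo)) / (u(d_hi) - u(d_lo))

where d_lo and d_hi are the lowest and highest dosages in the design.
Anchoring the curve *values* (rather than its asymptotes) to the condition
means keeps the ED50 and Hill-exponent estimates unbiased when the response
has not saturated within the observed dosage range.

The three-parameter form is used only when it improves AIC by more than 2.
AIC for least squares is ``n*ln(RSS/n) + 2k`` (additive constants cancel in
differences).  ED50 is the dosage at which the response crosses half of its
fitted range: low ED50 means the feature is buffered (little change until
the TF is strongly depleted), high ED50 means it is sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HillFit",
    "SensitivityCall",
    "MedianDosageCurve",
    "fit_dose_response",
    "classify_sensitivity",
    "buffering_index",
    "median_dosage_curve",
    "estimate_relative_dosage",
]

ED50_BOUNDS = (0.1, 500.0)
HILL_BOUNDS = (0.1, 20.0)
DEFAULT_STARTS = (20.0, 50.0, 80.0)


@dataclass
class HillFit:
    """Fitted dose-response for one feature."""

    feature_id: str | None
    model: str  # "linear", "hill2" or "hill3"
    y0: float  # asymptote at 0% dosage (fixed to the depletion-condition mean)
    y100: float  # value at 100% dosage (fixed for hill2, free for hill3)
    ed50: float
    hill_exponent: float
    slope: float
    intercept: float
    aic_linear: float
    aic_hill2: float
    aic_hill3: float
    aic_hill: float
    delta_aic: float  # AIC(linear) - AIC(selected Hill)
    p_ed50: float
    p_hill: float
    converged: bool
    n_points_used: int
    direction: str  # "down": abundance falls on depletion; "up": rises
    d_lo: float = 0.0  # depletion anchor dosage (lowest observed)
    d_hi: float = 100.0  # no-depletion anchor dosage (highest observed)

    @property
    def good_fit(self) -> bool:
        return bool(self.converged and self.p_ed50 < 0.05 and self.p_hill < 0.05)

    def predict(self, d) -> np.ndarray:
        """Evaluate the selected model at dosages ``d`` (percent)."""
        d = np.asarray(d, dtype=float)
        if self.model == "linear":
            return self.slope * d + self.intercept
        return _hill_anchored(
            d, self.y0, self.y100, self.ed50, self.hill_exponent, self.d_lo, self.d_hi
        )


@dataclass
class SensitivityCall:
    feature_id: str | None
    ed50: float
    sensitivity_class: str  # "buffered" | "moderate" | "high" | "unclassified"


@dataclass
class MedianDosageCurve:
    group_id: str
    median_ed50: float
    median_hill: float
    grid: np.ndarray
    values: np.ndarray  # normalized response in [0, 1]


def _hill_u(d, ed50, h):
    d = np.asarray(d, dtype=float)
    u = np.zeros_like(d)
    pos = d > 0
    u[pos] = d[pos] ** h / (ed50**h + d[pos] ** h)
    return u


def _hill(d, y0, y100, ed50, h):
    """Raw Hill form with asymptotes y0 (at 0) and y100 (at infinity)."""
    return y0 + (y100 - y0) * _hill_u(d, ed50, h)


def _hill_anchored(d, y_lo, y_hi, ed50, h, d_lo, d_hi):
    """Hill curve rescaled to pass through y_lo at d_lo and y_hi at d_hi."""
    u = _hill_u(d, ed50, h)
    u_lo = float(_hill_u(np.array([d_lo]), ed50, h)[0])
    u_hi = float(_hill_u(np.array([d_hi]), ed50, h)[0])
    span = max(u_hi - u_lo, 1e-12)  # degenerate when h -> 0 or ed50 -> inf
    return y_lo + (y_hi - y_lo) * (u - u_lo) / span


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _fit_hill(d, y, y0, y100_init, free_max, starts, d_lo, d_hi):
    """Bounded nonlinear least squares with analytic Jacobian and multistart.

    Parameters are (ed50, h) or (ed50, h, y100).  Ties between starts break
    toward the lowest ED50 start (strict-improvement scan in start order).
    """
    pos = d > 0
    logd = np.where(pos, np.log(np.where(pos, d, 1.0)), 0.0)
    log_lo, log_hi = np.log(d_lo), np.log(d_hi)

    def _parts(ed50, h):
        u = _hill_u(d, ed50, h)
        u_lo = d_lo**h / (ed50**h + d_lo**h)
        u_hi = d_hi**h / (ed50**h + d_hi**h)
        return u, u_lo, u_hi

    def residual(theta):
        ed50, h = theta[0], theta[1]
        y100 = theta[2] if free_max else y100_init
        u, u_lo, u_hi = _parts(ed50, h)
        # span degenerates when h -> 0 or ed50 far outside the dosage range
        span = max(u_hi - u_lo, 1e-12)
        return y0 + (y100 - y0) * (u - u_lo) / span - y

    def jac(theta):
        ed50, h = theta[0], theta[1]
        y100 = theta[2] if free_max else y100_init
        u, u_lo, u_hi = _parts(ed50, h)
        span = max(u_hi - u_lo, 1e-12)
        w = (u - u_lo) / span
        # du/de = -u(1-u)h/e ; du/dh = u(1-u)(ln d - ln e)
        du_e = -u * (1 - u) * h / ed50
        dlo_e = -u_lo * (1 - u_lo) * h / ed50
        dhi_e = -u_hi * (1 - u_hi) * h / ed50
        du_h = u * (1 - u) * (logd - np.log(ed50))
        dlo_h = u_lo * (1 - u_lo) * (log_lo - np.log(ed50))
        dhi_h = u_hi * (1 - u_hi) * (log_hi - np.log(ed50))
        amp = y100 - y0
        dw_e = (du_e - dlo_e - w * (dhi_e - dlo_e)) / span
        dw_h = (du_h - dlo_h - w * (dhi_h - dlo_h)) / span
        cols = [amp * dw_e, amp * dw_h]
        if free_max:
            cols.append(w)
        return np.column_stack(cols)

    lb = [ED50_BOUNDS[0], HILL_BOUNDS[0]]
    ub = [ED50_BOUNDS[1], HILL_BOUNDS[1]]
    if free_max:
        lb.append(-np.inf)
        ub.append(np.inf)

    best = None
    for s in starts:
        x0 = [float(np.clip(s, *ED50_BOUNDS)), 2.0]
        if free_max:
            x0.append(y100_init)
        try:
            res = optimize.least_squares(
                residual, x0, jac=jac, bounds=(lb, ub),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        rss = 2 * res.cost
        if best is None or rss < best[0] - 1e-14:
            best = (rss, res)
    return best


def _param_pvalues(res, rss, n, k):
    """Two-sided p-values from the asymptotic covariance of the fit."""
    dof = n - k
    if dof <= 0 or rss <= 0:
        return np.full(len(res.x), np.nan)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        return np.full(len(res.x), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(res.x) / se
    return 2 * stats.t.sf(t, dof)


def fit_dose_response(
    values,
    dosages,
    feature_id: str | None = None,
    starts=DEFAULT_STARTS,
    variant: str | None = None,
) -> HillFit:
    """Fit linear and Hill dose-response models to one feature.

    ``values`` may contain NaN (masked outliers); ``dosages`` are percent of
    the unperturbed TF level.  The Hill asymptote at depletion is fixed to
    the mean at the lowest observed dosage (the depletion anchor when no
    true 0% sample exists) and the full-dosage asymptote to the mean at the
    highest dosage; ``variant`` forces "hill2"/"hill3" (used by bootstrap
    refits), otherwise hill3 is selected when its AIC beats hill2 by > 2.

    Non-convergence is flagged on the returned fit, never raised.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(y) & np.isfinite(d)
    y, d = y[ok], d[ok]
    n = y.size
    levels = np.unique(d)
    if levels.size < 5:
        raise ValueError("need >= 5 distinct dosage levels after outlier removal")

    slope, intercept = np.polyfit(d, y, 1)
    rss_lin = float(np.sum((slope * d + intercept - y) ** 2))
    aic_lin = _aic(rss_lin, n, 2)

    if np.ptp(y) == 0:
        return HillFit(
            feature_id=feature_id, model="linear", y0=y[0], y100=y[0],
            ed50=np.nan, hill_exponent=np.nan, slope=0.0, intercept=float(y[0]),
            aic_linear=aic_lin, aic_hill2=np.nan, aic_hill3=np.nan,
            aic_hill=np.nan, delta_aic=np.nan, p_ed50=np.nan, p_hill=np.nan,
            converged=False, n_points_used=n, direction="down",
            d_lo=float(levels[0]), d_hi=float(levels[-1]),
        )

    d_lo, d_hi = float(levels[0]), float(levels[-1])
    y0_fix = float(y[d == levels[0]].mean())
    y100_fix = float(y[d == levels[-1]].mean())

    fits = {}
    if variant in (None, "hill2"):
        fits["hill2"] = _fit_hill(d, y, y0_fix, y100_fix, False, starts, d_lo, d_hi)
    if variant in (None, "hill3"):
        fits["hill3"] = _fit_hill(d, y, y0_fix, y100_fix, True, starts, d_lo, d_hi)

    aic2 = aic3 = np.nan
    if fits.get("hill2") is not None:
        aic2 = _aic(fits["hill2"][0], n, 2)
    if fits.get("hill3") is not None:
        aic3 = _aic(fits["hill3"][0], n, 3)

    if variant is None:
        use3 = np.isfinite(aic3) and (not np.isfinite(aic2) or aic3 < aic2 - 2)
        model = "hill3" if use3 else "hill2"
    else:
        model = variant
    chosen = fits.get(model)

    if chosen is None:
        return HillFit(
            feature_id=feature_id, model="linear", y0=y0_fix, y100=y100_fix,
            ed50=np.nan, hill_exponent=np.nan, slope=float(slope),
            intercept=float(intercept), aic_linear=aic_lin, aic_hill2=aic2,
            aic_hill3=aic3, aic_hill=np.nan, delta_aic=np.nan,
            p_ed50=np.nan, p_hill=np.nan, converged=False,
            n_points_used=n, direction="down" if y100_fix >= y0_fix else "up",
            d_lo=d_lo, d_hi=d_hi,
        )

    rss, res = chosen
    k = 3 if model == "hill3" else 2
    aic_hill = _aic(rss, n, k)
    pvals = _param_pvalues(res, rss, n, k)
    ed50, h = float(res.x[0]), float(res.x[1])
    y100 = float(res.x[2]) if model == "hill3" else y100_fix
    converged = bool(res.success and np.isfinite(rss))

    return HillFit(
        feature_id=feature_id, model=model, y0=y0_fix, y100=y100,
        ed50=ed50, hill_exponent=h, slope=float(slope), intercept=float(intercept),
        aic_linear=aic_lin, aic_hill2=aic2, aic_hill3=aic3, aic_hill=aic_hill,
        delta_aic=aic_lin - aic_hill, p_ed50=float(pvals[0]), p_hill=float(pvals[1]),
        converged=converged, n_points_used=n,
        direction="down" if y100 >= y0_fix else "up",
        d_lo=d_lo, d_hi=d_hi,
    )


def classify_sensitivity(
    fit: HillFit, thresholds: tuple[float, float] = (30.0, 40.0)
) -> SensitivityCall:
    """Bin a fit by ED50: < 30 buffered, 30-40 (closed) moderate, > 40 high."""
    lo, hi = thresholds
    if not fit.converged or not np.isfinite(fit.ed50):
        return SensitivityCall(fit.feature_id, np.nan, "unclassified")
    if fit.ed50 < lo:
        cls = "buffered"
    elif fit.ed50 <= hi:
        cls = "moderate"
    else:
        cls = "high"
    return SensitivityCall(fit.feature_id, fit.ed50, cls)


def buffering_index(fit: HillFit, dosage: float) -> float:
    """Percent of the total TF-dependent change still to come below ``dosage``.

    BI(d) = 100 - 100 * (f(100) - f(d)) / (f(100) - f(0)) on the fitted
    curve: 0 means no buffering (the full response has already occurred by
    dosage d), 100 means complete buffering (no change above d).
    """
    if not fit.converged:
        raise ValueError("buffering index requires a converged fit")
    f100 = float(fit.predict(100.0))
    f0 = float(fit.predict(0.0))
    total = f100 - f0
    if total == 0:
        raise ValueError("flat fitted curve: total TF-dependent change is zero")
    fd = float(fit.predict(float(dosage)))
    return 100.0 - 100.0 * (f100 - fd) / total


def median_dosage_curve(fits, grid=None, group_id: str = "group") -> MedianDosageCurve:
    """Group-summary Hill curve from the median fitted ED50 and exponent.

    The curve is the normalized two-parameter Hill response
    ``d^h / (ED50^h + d^h)`` with the group medians plugged in, so its value
    at the median ED50 is exactly 0.5.
    """
    fits = [f for f in fits if f.converged and np.isfinite(f.ed50)]
    if not fits:
        raise ValueError("no converged fits in group")
    if grid is None:
        grid = np.linspace(0.0, 100.0, 101)
    med_e = float(np.median([f.ed50 for f in fits]))
    med_h = float(np.median([f.hill_exponent for f in fits]))
    values = _hill(np.asarray(grid, dtype=float), 0.0, 1.0, med_e, med_h)
    # renormalize so the grid maximum is exactly 1 on a [0, 100] grid
    return MedianDosageCurve(group_id, med_e, med_h, np.asarray(grid, float), values)


def estimate_relative_dosage(
    gmfi_treated: float, gmfi_untreated: float, gmfi_wt: float
) -> float:
    """Relative TF dosage (percent) from geometric mean fluorescence.

    Background (the untagged wild-type sample's signal) is subtracted from
    both the treated and untreated tagged samples before taking their ratio.
    Values above 100 are kept (with a warning) up to a 110 cap; negatives
    clip to 0.
    """
    if gmfi_untreated <= gmfi_wt:
        raise ValueError("untreated signal must exceed the wild-type background")
    pct = 100.0 * (gmfi_treated - gmfi_wt) / (gmfi_untreated - gmfi_wt)
    if pct > 100.0:
        warnings.warn(f"estimated dosage {pct:.1f}% exceeds 100%; clipping at 110")
    return float(np.clip(pct, 0.0, 110.0))
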