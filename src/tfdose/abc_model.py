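"""Activity-by-contact propagation of RE fold changes to genes.

Each regulatory element (RE) within 5 Mb of a gene's TSS contributes in
proportion to its baseline activity sqrt(ATAC x H3K27ac) times a distance
power law dist^-0.7 standing in for 3D contact; contributions are
normalized per gene so ABC scores sum to 1.  The gene's predicted fold
change at a given TF dosage is then the ABC-weighted mean of its REs'
(linear-scale) fold changes.  A gene's own promoter (an RE within 1 kb of
the TSS) is excluded, which also guards the power law's divergence at
zero distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_abc_scores",
    "predict_gene_fold_change",
    "stratify_predicted_responses",
]

WINDOW_DEFAULT = 5_000_000
PROMOTER_EXCLUSION_DEFAULT = 1_000
CONTACT_EXPONENT = 0.7


def compute_abc_scores(
    res: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = WINDOW_DEFAULT,
    promoter_exclusion: int = PROMOTER_EXCLUSION_DEFAULT,
    contact_exponent: float = CONTACT_EXPONENT,
) -> pd.DataFrame:
    """RE-gene links with normalized ABC scores.

    ``res`` needs columns re_id, chrom, position (midpoint, 0-based) — or
    start/end, from which the midpoint is taken — plus baseline_atac and
    baseline_k27ac.  ``genes`` needs gene_id, chrom, tss.  For each gene,
    REs with promoter_exclusion < |midpoint - TSS| <= window on the same
    chromosome are scored dist^-exponent * sqrt(atac * k27ac) and
    normalized to sum 1 per gene.  Genes with no qualifying RE appear in
    the result with an empty link set (no rows).
    """
    res = res.copy()
    if "position" not in res.columns:
        res["position"] = (res["start"] + res["end"]) // 2
    if (res["baseline_atac"] < 0).any() or (res["baseline_k27ac"] < 0).any():
        raise ValueError("baseline activities must be non-negative")

    rows = []
    for _, g in genes.iterrows():
        sub = res[res["chrom"] == g["chrom"]]
        dist = (sub["position"] - g["tss"]).abs()
        keep = (dist > promoter_exclusion) & (dist <= window)
        sub = sub[keep]
        if sub.empty:
            continue
        dd = dist[keep].to_numpy(dtype=float)
        activity = np.sqrt(sub["baseline_atac"].to_numpy() * sub["baseline_k27ac"].to_numpy())
        raw = dd ** (-contact_exponent) * activity
        for re_id, dij, act, con, sc in zip(
            sub["re_id"], dd, activity, dd ** (-contact_exponent), raw / raw.sum()
        ):
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "re_id": re_id,
                    "distance": float(dij),
                    "activity": float(act),
                    "contact": float(con),
                    "abc_score": float(sc),
                }
            )
    links = pd.DataFrame(rows, columns=["gene_id", "re_id", "distance", "activity",
                                        "contact", "abc_score"])
    links.attrs["genes_without_links"] = sorted(
        set(genes["gene_id"]) - set(links["gene_id"])
    )
    return links


def predict_gene_fold_change(
    links: pd.DataFrame,
    re_fc: pd.DataFrame,
    condition: float | None = None,
    max_missing_mass: float = 0.5,
) -> pd.DataFrame:
    """ABC-weighted gene fold-change predictions for one condition.

    ``re_fc`` is long format (re_id, condition, fc) or, if ``condition`` is
    None and it has no condition column, a two-column (re_id, fc) table.
    For each linked gene, prediction = sum(ABC * fc) / sum(ABC) over REs
    with an available fold change; the explicit renormalization matters
    only when some REs are missing.  Predictions relying on less than half
    a gene's ABC mass are flagged low-confidence.
    """
    if condition is not None:
        fc = re_fc[re_fc["condition"] == condition]
    else:
        fc = re_fc
    fc_map = fc.set_index("re_id")["fc"]
    if (fc_map <= 0).any():
        raise ValueError("fold changes must be positive (linear scale)")

    out = []
    for gid, grp in links.groupby("gene_id", sort=True):
        have = grp["re_id"].isin(fc_map.index)
        mass = grp.loc[have, "abc_score"].sum()
        if mass == 0:
            out.append({"gene_id": gid, "predicted_fc": np.nan, "abc_mass_used": 0.0,
                        "low_confidence": True})
            continue
        w = grp.loc[have, "abc_score"].to_numpy()
        f = fc_map[grp.loc[have, "re_id"]].to_numpy(dtype=float)
        out.append(
            {
                "gene_id": gid,
                "predicted_fc": float(np.sum(w * f) / np.sum(w)),
                "abc_mass_used": float(mass),
                "low_confidence": bool(mass < (1.0 - max_missing_mass)),
            }
        )
    return pd.DataFrame(out, columns=["gene_id", "predicted_fc", "abc_mass_used",
                                      "low_confidence"])


def _normalized_log_response(fc_table: pd.DataFrame, full_depletion: float) -> pd.DataFrame:
    """Per gene, log fold change at each condition divided by the log fold
    change at full depletion (the lowest dosage)."""
    wide = fc_table.pivot(index="gene_id", columns="condition", values="fc")
    logw = np.log2(wide)
    denom = logw[full_depletion]
    norm = logw.div(denom, axis=0)
    norm = norm[np.isfinite(denom) & (denom != 0)]
    return norm


def stratify_predicted_responses(
    responses: pd.DataFrame,
    ed50_by_gene: pd.Series,
    thresholds: tuple[float, float] = (30.0, 40.0),
    min_bin_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify normalized responses by gene ED50 and test bin separation.

    ``responses`` is a long (gene_id, condition, fc) table — observed or
    predicted fold changes vs the 100% condition.  Each gene's log fold
    change is normalized by its full-depletion (lowest dosage) log fold
    change; genes are binned by ED50 into < lo, [lo, hi], > hi.  Per
    intermediate condition the median and quartiles per bin are reported
    together with a Kruskal-Wallis p-value across bins with at least
    ``min_bin_size`` genes (NaN when fewer than two such bins).
    """
    conds = np.sort(responses["condition"].unique())
    full_dep = conds[0]
    norm = _normalized_log_response(responses, full_dep)
    lo, hi = thresholds
    ed50 = ed50_by_gene.reindex(norm.index)
    bins = pd.cut(ed50, [-np.inf, lo, hi, np.inf], right=True,
                  labels=["buffered", "moderate", "high"])
    # pd.cut's right-closed bins put ED50 == lo in "buffered"; the class
    # convention is the closed interval [lo, hi] -> moderate
    bins = bins.where(ed50 != lo, "moderate")

    table_rows, test_rows = [], []
    for c in conds:
        if c == 100.0:
            continue
        groups = []
        for b in ["buffered", "moderate", "high"]:
            vals = norm.loc[(bins == b).to_numpy(), c].dropna().to_numpy()
            table_rows.append(
                {
                    "condition": c,
                    "bin": b,
                    "n": vals.size,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "q25": float(np.percentile(vals, 25)) if vals.size else np.nan,
                    "q75": float(np.percentile(vals, 75)) if vals.size else np.nan,
                }
            )
            if vals.size >= min_bin_size:
                groups.append(vals)
        if len(groups) >= 2:
            try:
                p = float(stats.kruskal(*groups).pvalue)
            except ValueError:  # all values identical
                p = np.nan
        else:
            p = np.nan
        test_rows.append({"condition": c, "kruskal_p": p})
    return pd.DataFrame(table_rows), pd.DataFrame(test_rows)
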