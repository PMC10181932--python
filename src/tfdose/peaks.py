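"""Reproducible consensus peak regions from replicate summit calls.

Two-stage merge of ATAC summit positions: within each replicate, summits
whose consecutive sorted gaps are <= 75 bp are single-linkage clustered and
replaced by their rounded mean position; then, across all replicates'
merged summits, the same clustering with a 150 bp window is applied and
clusters supported by summits from at least three distinct
differentiation/line instances are kept.  Supported summits are extended
250 bp in either direction and overlapping or adjacent regions merged into
sorted, disjoint intervals (0-based half-open throughout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "merge_summits_within_replicate",
    "merge_across_replicates",
    "build_consensus_regions",
    "call_consensus_peaks",
    "read_summits_bed",
    "write_consensus_bed",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _cluster_positions(pos: np.ndarray, window: int) -> list[np.ndarray]:
    """Single-linkage clusters of sorted positions: a new cluster starts
    whenever the gap to the previous position exceeds ``window``."""
    order = np.argsort(pos, kind="stable")
    sp = pos[order]
    if sp.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(sp) > window) + 1
    return [order[idx] for idx in np.split(np.arange(sp.size), breaks)]


def merge_summits_within_replicate(summits: pd.DataFrame, window: int = 75) -> pd.DataFrame:
    """Merge nearby summits separately within each replicate.

    ``summits`` needs chrom, position, replicate, differentiation columns.
    Clusters (consecutive sorted gaps <= window, per chrom and replicate)
    are replaced by their mean position rounded half-up; the constituent
    count is retained.
    """
    rows = []
    for (rep, chrom), grp in summits.groupby(["replicate", "chrom"], sort=True):
        diff = grp["differentiation"].iloc[0]
        pos = grp["position"].to_numpy(dtype=np.int64)
        for idx in _cluster_positions(pos, window):
            rows.append(
                {
                    "chrom": chrom,
                    "position": _round_half_up(pos[idx].mean()),
                    "replicate": rep,
                    "differentiation": diff,
                    "n_constituent": len(idx),
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "position", "replicate",
                                      "differentiation", "n_constituent"])
    return out.sort_values(["chrom", "position", "replicate"], ignore_index=True)


def merge_across_replicates(
    merged: pd.DataFrame, window: int = 150, min_support: int = 3
) -> pd.DataFrame:
    """Merge per-replicate summits across the whole dataset and filter by
    differentiation support.

    Clusters (150 bp single linkage per chrom, across all replicates) are
    replaced by their rounded mean position and kept only when their
    constituents come from >= ``min_support`` distinct differentiation/line
    instances.
    """
    rows = []
    for chrom, grp in merged.groupby("chrom", sort=True):
        pos = grp["position"].to_numpy(dtype=np.int64)
        diffs = grp["differentiation"].to_numpy()
        for idx in _cluster_positions(pos, window):
            support = len(set(diffs[idx]))
            if support >= min_support:
                rows.append(
                    {
                        "chrom": chrom,
                        "position": _round_half_up(pos[idx].mean()),
                        "n_support": support,
                    }
                )
    out = pd.DataFrame(rows, columns=["chrom", "position", "n_support"])
    return out.sort_values(["chrom", "position"], ignore_index=True)


def build_consensus_regions(supported: pd.DataFrame, extend: int = 250) -> pd.DataFrame:
    """Extend supported summits +/- ``extend`` bp and merge into disjoint
    regions (overlapping or book-ended intervals are unioned; n_support is
    the max over merged constituents).  Intervals are 0-based half-open and
    clipped at zero."""
    rows = []
    for chrom, grp in supported.groupby("chrom", sort=True):
        grp = grp.sort_values("position")
        start = np.maximum(grp["position"].to_numpy(dtype=np.int64) - extend, 0)
        end = grp["position"].to_numpy(dtype=np.int64) + extend + 1
        sup = grp["n_support"].to_numpy()
        cur_s, cur_e, cur_n = None, None, 0
        for s, e, n in zip(start, end, sup):
            if cur_s is None:
                cur_s, cur_e, cur_n = s, e, n
            elif s <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, e)
                cur_n = max(cur_n, n)
            else:
                rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e),
                             "n_support": int(cur_n)})
                cur_s, cur_e, cur_n = s, e, n
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": int(cur_s), "end": int(cur_e),
                         "n_support": int(cur_n)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_support"])


def call_consensus_peaks(
    summits: pd.DataFrame,
    within_window: int = 75,
    across_window: int = 150,
    min_support: int = 3,
    extend: int = 250,
) -> pd.DataFrame:
    """Full two-stage pipeline: within-replicate merge, cross-replicate
    merge with support filter, extension and region union."""
    merged = merge_summits_within_replicate(summits, window=within_window)
    supported = merge_across_replicates(merged, window=across_window,
                                        min_support=min_support)
    return build_consensus_regions(supported, extend=extend)


def read_summits_bed(path) -> pd.DataFrame:
    """Read BED6 summit calls; the name field is ``replicate:differentiation``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 3], names=["chrom", "position", "name"])
    rep_diff = df["name"].str.split(":", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "position": df["position"].astype(np.int64),
            "replicate": rep_diff[0],
            "differentiation": rep_diff[1],
        }
    )


def write_consensus_bed(peaks: pd.DataFrame, path, header_lines=()) -> None:
    """Write consensus regions as BED4 with n_support in the name column."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for _, r in peaks.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['n_support']}\n")
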