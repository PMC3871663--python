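"""Windowed F_ST differentiation scans between cultivated groups.

Hudson ratio-of-sums F_ST per sliding window, for the indica-japonica and
temperate-tropical japonica comparisons (any two mapped groups work).
Peaks are reported descriptively as in the source procedure; an optional
label-permutation null provides an empirical significance threshold (an
artifact addition, flagged as such in output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats


@dataclass
class FstRegion:
    label: str
    chrom: str
    start: int
    end: int
    n_windows: int
    peak_fst: float


def fst_scan(panel, popmap, pop_a: str, pop_b: str,
             grid: stats.WindowGrid) -> pd.DataFrame:
    """Per-window Hudson F_ST track; windows without a scorable site
    (fewer than 2 called samples in either population) are undefined."""
    for pop in (pop_a, pop_b):
        if len(stats.pop_rows(panel, popmap, pop)) < 2:
            raise ValueError(f"population {pop!r} unknown or has <2 samples")
    pos, alleles = stats.panel_arrays(panel, grid.chrom)
    ra = stats.pop_rows(panel, popmap, pop_a)
    rb = stats.pop_rows(panel, popmap, pop_b)
    within, between, valid = stats.fst_site_components(alleles[ra],
                                                       alleles[rb])
    w_sum, _ = stats.window_sums(pos, within, grid)
    b_sum, _ = stats.window_sums(pos, between, grid)
    n_valid, _ = stats.window_sums(pos, valid.astype(float), grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(b_sum > 0, 1.0 - w_sum / b_sum, np.nan)
    fst = np.where(n_valid > 0, fst, np.nan)
    return pd.DataFrame({
        "chrom": grid.chrom, "start": grid.starts, "end": grid.ends,
        "truncated": grid.truncated, "n_sites": n_valid.astype(int),
        "fst": fst,
    })


def top_fst_regions(track: pd.DataFrame, K: int = 1,
                    exclude_truncated: bool = True,
                    prefix: str = "F") -> list[FstRegion]:
    """Top-K peak windows (highest F_ST, ties to the leftmost window),
    merged when overlapping or abutting.  Negative-F_ST windows never
    rank as peaks."""
    t = track.copy()
    if exclude_truncated:
        t = t[~t["truncated"]]
    t = t[np.isfinite(t["fst"]) & (t["fst"] > 0)]
    if not len(t):
        return []
    t = t.sort_values(["fst", "chrom", "start"],
                      ascending=[False, True, True], kind="stable")
    picked = t.head(K).sort_values(["chrom", "start"])
    regions = []
    cur = None
    for _, w in picked.iterrows():
        if (cur is not None and w["chrom"] == cur["chrom"]
                and w["start"] <= cur["end"]):
            cur["end"] = max(cur["end"], int(w["end"]))
            cur["n_windows"] += 1
            cur["peak_fst"] = max(cur["peak_fst"], float(w["fst"]))
        else:
            if cur is not None:
                regions.append(cur)
            cur = {"chrom": w["chrom"], "start": int(w["start"]),
                   "end": int(w["end"]), "n_windows": 1,
                   "peak_fst": float(w["fst"])}
    regions.append(cur)
    regions.sort(key=lambda r: (-r["peak_fst"], r["chrom"], r["start"]))
    return [FstRegion(label=f"{prefix}{i + 1:02d}", **r)
            for i, r in enumerate(regions)]


def permutation_threshold(panel, popmap, pop_a: str, pop_b: str,
                          grid: stats.WindowGrid, n_perm: int = 20,
                          quantile: float = 0.99, seed=None) -> float:
    """Empirical window-F_ST threshold under label permutation (panmictic
    null).  Returns the requested quantile of the permuted window values."""
    rng = np.random.default_rng(seed)
    ra = stats.pop_rows(panel, popmap, pop_a)
    rb = stats.pop_rows(panel, popmap, pop_b)
    pool = np.concatenate([ra, rb])
    pos, alleles = stats.panel_arrays(panel, grid.chrom)
    vals = []
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        pa, pb = perm[:len(ra)], perm[len(ra):]
        within, between, valid = stats.fst_site_components(alleles[pa],
                                                           alleles[pb])
        w_sum, _ = stats.window_sums(pos, within, grid)
        b_sum, _ = stats.window_sums(pos, between, grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(b_sum > 0, 1.0 - w_sum / b_sum, np.nan)
        vals.append(fst[np.isfinite(fst)])
    allv = np.concatenate(vals)
    if not len(allv):
        return float("nan")
    return float(np.quantile(allv, quantile))
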