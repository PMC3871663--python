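"""Simulation-null diversity-ratio scan for selective sweeps.

A null distribution of the cultivated/wild diversity ratios (pi-based and
Watterson-based) over window-sized neutral loci is built by coalescent
simulation under the fitted bottleneck model.  Each observed window's ratio
is converted to an empirical tail probability
p = (#{simulated <= observed} + 1) / (R + 1) and scored logP = -log10(p);
windows ranking in the top K by BOTH measures are merged into candidate
sweep regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simdata import DemographicModel, simulate_locus

log = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    model: DemographicModel
    n_wild: int
    n_cult: int
    window: int
    R: int
    ratios_pi: np.ndarray     # sorted ascending
    ratios_theta: np.ndarray  # sorted ascending
    seed: int | None
    n_redrawn: int = 0


@dataclass
class SweepRegion:
    label: str
    chrom: str
    start: int
    end: int
    n_windows: int
    best_logp_pi: float
    best_logp_theta: float
    rank_pi: int
    rank_theta: int


def regions_to_frame(regions) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in regions], columns=[
        "label", "chrom", "start", "end", "n_windows", "best_logp_pi",
        "best_logp_theta", "rank_pi", "rank_theta"])


def simulate_window_ratios(model: DemographicModel, n_wild: int,
                           n_cult: int, window: int, rng,
                           locus_size: int | None = None):
    """Diversity ratios of one neutral window replicate.

    With ``locus_size`` the window is stitched from independently
    simulated loci (free recombination between them), matching the
    construction of the synthetic genome; None simulates the window as a
    single fully linked locus.  Returns None when the wild sample carries
    no diversity in the replicate.
    """
    sizes = ([window] if not locus_size else
             [min(locus_size, window - s)
              for s in range(0, window, locus_size)])
    pi_w = pi_c = th_w = th_c = 0.0
    for L in sizes:
        panel = simulate_locus(model, n_wild, n_cult, L,
                               seed=int(rng.integers(2**31)))
        dw, cw = stats.allele_counts(panel.alleles[:n_wild])
        dc, cc = stats.allele_counts(panel.alleles[n_wild:])
        pi_w += stats._site_pi_vec(dw, cw).sum()
        pi_c += stats._site_pi_vec(dc, cc).sum()
        th_w += stats._site_theta_vec(dw, cw).sum()
        th_c += stats._site_theta_vec(dc, cc).sum()
    if pi_w <= 0 or th_w <= 0:
        return None
    return pi_c / pi_w, th_c / th_w


def build_null_distribution(model: DemographicModel, n_wild: int,
                            n_cult: int, window: int, R: int,
                            seed=None,
                            locus_size: int | None = None
                            ) -> NullDistribution:
    """R neutral window-sized replicates of the diversity ratios.

    Replicates with zero wild diversity are re-drawn (count logged).
    """
    if model.T1 is None:
        raise ValueError("null model must be a two-population model")
    rng = np.random.default_rng(seed)
    rp = np.empty(R)
    rt = np.empty(R)
    n_redrawn = 0
    for r in range(R):
        while True:
            out = simulate_window_ratios(model, n_wild, n_cult, window,
                                         rng, locus_size)
            if out is not None:
                rp[r], rt[r] = out
                break
            n_redrawn += 1
    if n_redrawn:
        log.info("null distribution: re-drew %d replicates with zero wild "
                 "diversity", n_redrawn)
    return NullDistribution(model, n_wild, n_cult, window, R,
                            np.sort(rp), np.sort(rt), seed, n_redrawn)


def ratio_track(panel, popmap, grid: stats.WindowGrid, cult_group: str,
                wild_group: str,
                site_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-window diversity of both groups plus the scan ratios."""
    cult = stats.window_diversity(panel, popmap, grid, cult_group,
                                  site_mask=site_mask)
    wild = stats.window_diversity(panel, popmap, grid, wild_group,
                                  site_mask=site_mask)
    track = cult[["chrom", "start", "end", "truncated", "callable"]].copy()
    track["n_snps"] = cult["n_snps"] + wild["n_snps"]
    track["pi_cult"] = cult["pi"]
    track["pi_wild"] = wild["pi"]
    track["theta_cult"] = cult["theta"]
    track["theta_wild"] = wild["theta"]
    with np.errstate(divide="ignore", invalid="ignore"):
        track["ratio_pi"] = np.where(wild["pi"] > 0,
                                     cult["pi"] / wild["pi"], np.nan)
        track["ratio_theta"] = np.where(wild["theta"] > 0,
                                        cult["theta"] / wild["theta"],
                                        np.nan)
    return track


def score_windows(track: pd.DataFrame, null: NullDistribution,
                  window: int | None = None) -> pd.DataFrame:
    """Attach logP columns: empirical tail probability of each ratio."""
    sizes = (track["end"] - track["start"])[~track["truncated"]]
    if window is None and len(sizes):
        window = int(sizes.iloc[0])
    if window is not None and window != null.window:
        raise ValueError(f"track windows are {window} bp but the null was "
                         f"built for {null.window} bp")
    out = track.copy()
    for col, ref in (("ratio_pi", null.ratios_pi),
                     ("ratio_theta", null.ratios_theta)):
        obs = out[col].to_numpy(dtype=float)
        n_le = np.searchsorted(ref, obs, side="right")
        p = (n_le + 1.0) / (null.R + 1.0)
        lp = -np.log10(p)
        lp[~np.isfinite(obs)] = np.nan
        out["logp_pi" if col == "ratio_pi" else "logp_theta"] = lp
    return out


def _select_peaks(t: pd.DataFrame, logp_col: str, ratio_col: str,
                  K: int) -> dict[int, int]:
    """Greedy top-K non-overlapping peak windows for one measure.

    On an overlapping sliding grid the many windows covering one diversity
    trough are redundant; ranking therefore runs over distinct peaks: the
    best-scoring window is taken, every window overlapping it is shadowed,
    and selection continues.  Ties break toward the lower observed ratio,
    then the leftmost window.  Returns {row index: peak rank}.
    """
    score = t[logp_col].to_numpy(dtype=float)
    ratio = t[ratio_col].to_numpy(dtype=float)
    chrom = t["chrom"].to_numpy()
    start = t["start"].to_numpy(dtype=np.int64)
    end = t["end"].to_numpy(dtype=np.int64)
    # logP = 0 (p = 1) carries no evidence and never ranks as a peak
    order = sorted(
        (i for i in range(len(t)) if np.isfinite(score[i])
         and score[i] > 0),
        key=lambda i: (-score[i],
                       ratio[i] if np.isfinite(ratio[i]) else np.inf,
                       str(chrom[i]), int(start[i])))
    chosen: dict[int, int] = {}
    for i in order:
        if len(chosen) >= K:
            break
        if any(chrom[i] == chrom[j] and start[i] < end[j]
               and end[i] > start[j] for j in chosen):
            continue
        chosen[i] = len(chosen) + 1
    return chosen


def call_sweep_regions(track: pd.DataFrame, K: int = 15,
                       exclude_truncated: bool = True) -> list[SweepRegion]:
    """Candidate regions supported by the top K of BOTH logP measures.

    Top-K non-overlapping peak windows are selected separately for the
    pi-ratio and theta-ratio scores; a peak qualifies when it overlaps a
    peak of the other measure.  Qualifying windows that overlap or abut
    merge into regions labelled S01, S02, ... in genomic order.
    """
    t = track.copy()
    if exclude_truncated:
        t = t[~t["truncated"]].reset_index(drop=True)
    if not len(t) or t["logp_pi"].isna().all():
        return []
    peaks_pi = _select_peaks(t, "logp_pi", "ratio_pi", K)
    peaks_th = _select_peaks(t, "logp_theta", "ratio_theta", K)
    chrom = t["chrom"].to_numpy()
    start = t["start"].to_numpy(dtype=np.int64)
    end = t["end"].to_numpy(dtype=np.int64)

    def _overlaps_any(i, others):
        return any(chrom[i] == chrom[j] and start[i] < end[j]
                   and end[i] > start[j] for j in others)

    qual = sorted({i for i in peaks_pi if _overlaps_any(i, peaks_th)}
                  | {i for i in peaks_th if _overlaps_any(i, peaks_pi)},
                  key=lambda i: (str(chrom[i]), int(start[i])))
    if not qual:
        return []
    merged: list[list[int]] = []
    for i in qual:
        if (merged and chrom[i] == chrom[merged[-1][-1]]
                and start[i] <= end[merged[-1][-1]]):
            merged[-1].append(i)
        else:
            merged.append([i])
    regions = []
    for members in merged:
        regions.append(dict(
            chrom=str(chrom[members[0]]),
            start=int(min(start[i] for i in members)),
            end=int(max(end[i] for i in members)),
            n_windows=len(members),
            best_logp_pi=float(np.nanmax(
                t["logp_pi"].to_numpy()[members])),
            best_logp_theta=float(np.nanmax(
                t["logp_theta"].to_numpy()[members])),
            rank_pi=min((peaks_pi[i] for i in members if i in peaks_pi),
                        default=K + 1),
            rank_theta=min((peaks_th[i] for i in members if i in peaks_th),
                           default=K + 1),
        ))
    regions.sort(key=lambda r: (r["chrom"], r["start"]))
    return [SweepRegion(label=f"S{i + 1:02d}", **r)
            for i, r in enumerate(regions)]
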