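"""Diversity estimators on haploid-coded panels with missing data.

Per-site nucleotide diversity is the mean number of pairwise differences
among called alleles; Watterson's estimator uses the count of segregating
sites scaled by the harmonic number of the per-site called sample size.
Window values divide summed per-site quantities by the number of callable
sites in the window (by default the window span in bp; a site mask or
per-window callable count can be supplied instead).  F_ST is the Hudson
estimator in ratio-of-sums form, 1 - sum(within) / sum(between).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_HARMONIC_MAX = 4096
_A = np.concatenate([[0.0],
                     np.cumsum(1.0 / np.arange(1, _HARMONIC_MAX + 1))])


def harmonic_number(k):
    """a_k = sum_{i=1..k} 1/i, vectorized, a_0 = 0."""
    k = np.asarray(k)
    if np.any(k > _HARMONIC_MAX):
        raise ValueError("harmonic number table too small")
    return _A[k]


def watterson_theta(n_segregating: float, n_samples: int, length: float):
    """Genome/window-scale Watterson estimate S / (a_{n-1} * L)."""
    return n_segregating / (harmonic_number(n_samples - 1) * length)


def allele_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(derived count, called count) per site for a samples x sites matrix."""
    called = (alleles >= 0).sum(axis=0)
    derived = (alleles == 1).sum(axis=0)
    return derived, called


def site_pi(alleles_at_site: np.ndarray) -> float:
    """Mean pairwise difference at one site; NaN with fewer than 2 calls."""
    a = np.asarray(alleles_at_site)
    called = int((a >= 0).sum())
    if called < 2:
        return float("nan")
    d = int((a == 1).sum())
    return d * (called - d) / (called * (called - 1) / 2)


def _site_pi_vec(derived, called):
    pairs = called * (called - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(pairs > 0, derived * (called - derived) / pairs, 0.0)
    return pi


def _site_theta_vec(derived, called):
    seg = (derived > 0) & (derived < called)
    with np.errstate(divide="ignore"):
        w = np.where(seg & (called >= 2),
                     1.0 / harmonic_number(np.maximum(called - 1, 1)), 0.0)
    return w


@dataclass
class WindowGrid:
    """Sliding windows [start, start+size) stepped by ``step`` bp."""

    chrom: str
    size: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    truncated: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def sliding_windows(chrom_length: int, size: int, step: int,
                    chrom: str = "chr") -> WindowGrid:
    """Windows [k*step, k*step+size) for every start < chrom_length.

    Windows running past the chromosome end are truncated and flagged.
    """
    if size <= 0 or step <= 0 or step > size:
        raise ValueError("need 0 < step <= size")
    starts = np.arange(0, max(chrom_length, 1), step, dtype=np.int64)
    ends = np.minimum(starts + size, chrom_length)
    truncated = starts + size > chrom_length
    return WindowGrid(chrom, size, step, starts, ends, truncated)


def panel_arrays(panel, chrom: str | None = None):
    """(positions, alleles) for either a HaplotypePanel or GenotypePanel."""
    if hasattr(panel, "sites"):
        pos = panel.sites["pos"].to_numpy(dtype=np.int64)
        alleles = panel.alleles
        if chrom is not None:
            keep = (panel.sites["chrom"] == chrom).to_numpy()
            pos, alleles = pos[keep], alleles[:, keep]
        return pos, alleles
    return np.asarray(panel.positions, dtype=np.int64), panel.alleles


def pop_rows(panel, popmap, population: str) -> np.ndarray:
    if popmap is None and hasattr(panel, "populations"):
        return np.array([i for i, p in enumerate(panel.populations)
                         if p == population], dtype=int)
    return popmap.indices_in(panel.samples, population)


def window_sums(positions, values, grid: WindowGrid):
    """Sum ``values`` per window (overlap-aware via cumulative sums)."""
    order = np.argsort(positions, kind="stable")
    pos = np.asarray(positions)[order]
    cum = np.concatenate([[0.0], np.cumsum(np.asarray(values)[order])])
    i0 = np.searchsorted(pos, grid.starts, side="left")
    i1 = np.searchsorted(pos, grid.ends, side="left")
    return cum[i1] - cum[i0], i1 - i0


def window_diversity(panel, popmap, grid: WindowGrid, population: str,
                     site_mask: np.ndarray | None = None,
                     callable_bp: np.ndarray | None = None) -> pd.DataFrame:
    """Per-window pi and Watterson theta for one population.

    ``site_mask`` restricts to a subset of panel sites (e.g. gene regions);
    ``callable_bp`` overrides the per-window callable-site denominator
    (default: window span).
    """
    pos, alleles = panel_arrays(panel, grid.chrom)
    rows = pop_rows(panel, popmap, population)
    if rows.size < 2:
        raise ValueError(f"population {population!r} has <2 samples")
    sub = alleles[rows]
    if site_mask is not None:
        pos, sub = pos[site_mask], sub[:, site_mask]
    derived, called = allele_counts(sub)
    pi_site = _site_pi_vec(derived, called)
    th_site = _site_theta_vec(derived, called)
    seg = ((derived > 0) & (derived < called)).astype(float)
    pi_sum, _ = window_sums(pos, pi_site, grid)
    th_sum, _ = window_sums(pos, th_site, grid)
    n_seg, _ = window_sums(pos, seg, grid)
    if callable_bp is None:
        callable_bp = (grid.ends - grid.starts).astype(float)
    callable_bp = np.asarray(callable_bp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(callable_bp > 0, pi_sum / callable_bp, np.nan)
        theta = np.where(callable_bp > 0, th_sum / callable_bp, np.nan)
    return pd.DataFrame({
        "chrom": grid.chrom, "start": grid.starts, "end": grid.ends,
        "truncated": grid.truncated, "callable": callable_bp,
        "n_snps": n_seg.astype(int), "pi": pi, "theta": theta,
    })


def fst_site_components(alleles_a: np.ndarray, alleles_b: np.ndarray):
    """Per-site Hudson components (within, between, valid mask)."""
    da, ca = allele_counts(alleles_a)
    db, cb = allele_counts(alleles_b)
    valid = (ca >= 2) & (cb >= 2)
    within = 0.5 * (_site_pi_vec(da, ca) + _site_pi_vec(db, cb))
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(ca > 0, da / ca, np.nan)
        pb = np.where(cb > 0, db / cb, np.nan)
    between = pa * (1.0 - pb) + pb * (1.0 - pa)
    within = np.where(valid, within, 0.0)
    between = np.where(valid, between, 0.0)
    return within, between, valid


def hudson_fst(panel, popmap, pop_a: str, pop_b: str,
               chrom: str | None = None,
               region: tuple[int, int] | None = None) -> float:
    """Ratio-of-sums Hudson F_ST over all (or a region's) sites."""
    pos, alleles = panel_arrays(panel, chrom)
    ra = pop_rows(panel, popmap, pop_a)
    rb = pop_rows(panel, popmap, pop_b)
    sub_a, sub_b = alleles[ra], alleles[rb]
    if region is not None:
        keep = (pos >= region[0]) & (pos < region[1])
        sub_a, sub_b = sub_a[:, keep], sub_b[:, keep]
    within, between, valid = fst_site_components(sub_a, sub_b)
    bsum = between[valid].sum()
    if bsum <= 0:
        return float("nan")
    return 1.0 - within[valid].sum() / bsum


def per_gene_synonymous_pi(panel, annotation, popmap, population: str,
                           n_sites: int = 1000) -> pd.DataFrame:
    """Diversity over the first ``n_sites`` synonymous sites of each gene.

    Genes with fewer synonymous-class sites than ``n_sites`` are excluded
    (reason recorded).  Requires annotation.syn_sites (see
    annotate.attach_synonymous_sites).
    """
    if not annotation.syn_sites:
        raise ValueError("annotation has no synonymous-site map; "
                         "run annotate.attach_synonymous_sites first")
    rows_out = []
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gene in annotation.genes:
        syn = annotation.syn_sites.get(gene.gene_id)
        if syn is None or len(syn) < n_sites:
            rows_out.append((gene.gene_id, 0 if syn is None else len(syn),
                             np.nan, 0, 0, False, "too_few_synonymous_sites"))
            continue
        use = np.sort(np.asarray(syn[:n_sites]))
        if gene.chrom not in cache:
            pos, alleles = panel_arrays(panel, gene.chrom)
            prows = pop_rows(panel, popmap, population)
            cache[gene.chrom] = (pos, alleles[prows])
        pos, sub = cache[gene.chrom]
        hit = np.flatnonzero(np.isin(pos, use))
        derived, called = allele_counts(sub[:, hit])
        pi = _site_pi_vec(derived, called).sum() / n_sites
        seg = int(((derived > 0) & (derived < called)).sum())
        rows_out.append((gene.gene_id, len(syn), pi, seg, n_sites, True, ""))
    return pd.DataFrame(rows_out, columns=[
        "gene_id", "n_syn_sites", "pi", "n_segregating", "length",
        "included", "reason"])


def ld_r2_decay(panel, popmap, population: str, max_dist: int = 1_000_000,
                bin_size: int = 2000, subsample: int | None = None,
                seed: int | None = None,
                max_sites: int | None = None) -> pd.DataFrame:
    """Mean r^2 between SNP pairs, binned by physical distance.

    For every intra-chromosomal biallelic pair within ``max_dist``,
    r^2 = D^2 / (p1 q1 p2 q2) is computed on samples called at both sites,
    optionally after random subsampling to a common size (the convention
    used to equalize sample sizes across populations).  Pairs with fewer
    than 4 joint calls, or monomorphic after subsampling, are skipped.
    """
    rng = np.random.default_rng(seed)
    chroms = panel.chroms() if hasattr(panel, "chroms") else [None]
    n_bins = int(np.ceil(max_dist / bin_size)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in chroms:
        pos, alleles = panel_arrays(panel, chrom)
        rows = pop_rows(panel, popmap, population)
        sub = alleles[rows]
        derived, called = allele_counts(sub)
        keep = (derived > 0) & (derived < called)
        pos, sub = pos[keep], sub[:, keep]
        order = np.argsort(pos, kind="stable")
        pos, sub = pos[order], sub[:, order]
        if max_sites is not None and len(pos) > max_sites:
            pick = np.sort(rng.choice(len(pos), size=max_sites,
                                      replace=False))
            pos, sub = pos[pick], sub[:, pick]
        m = len(pos)
        for i in range(m):
            j = i + 1
            while j < m and pos[j] - pos[i] <= max_dist:
                r2 = _pair_r2(sub[:, i], sub[:, j], subsample, rng)
                if not np.isnan(r2):
                    b = int((pos[j] - pos[i]) // bin_size)
                    sums[b] += r2
                    counts[b] += 1
                j += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    left = np.arange(n_bins) * bin_size
    return pd.DataFrame({"dist_lo": left, "dist_hi": left + bin_size,
                         "mean_r2": mean, "n_pairs": counts})


def _pair_r2(a, b, subsample, rng) -> float:
    joint = (a >= 0) & (b >= 0)
    idx = np.flatnonzero(joint)
    if subsample is not None and len(idx) > subsample:
        idx = rng.choice(idx, size=subsample, replace=False)
    if len(idx) < 4:
        return float("nan")
    x, y = a[idx], b[idx]
    p1, p2 = x.mean(), y.mean()
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        return float("nan")
    d = (x & y).mean() - p1 * p2
    return float(d * d / denom)
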