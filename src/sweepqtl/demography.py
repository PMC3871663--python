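"""Simulation-based composite-likelihood inference of the bottleneck.

The data are per-locus segregating-site counts on fixed-length loci (the
first 1000 synonymous sites of each gene).  N0 is estimated first from the
wild sample alone: for each candidate N0 the distribution of S under a
constant-size coalescent with theta = 4*N0*mu per site is built by
simulation and the composite log-likelihood of the observed counts is
summed over loci.  With N0 fixed, a two-dimensional surface over (N1, T1)
is built the same way from the empirical conditional distribution
P(S_cult | S_wild) under the split-with-bottleneck model.  Loci are
treated as freely recombining between and non-recombining within
(composite likelihood); add-one smoothing keeps every cell finite.

Population sizes here are effective sizes: a selfing wild population of
census size N behaves as one of size N / (1 + F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusSummary:
    gene_id: str
    s_wild: int
    s_cult: int
    length: int = 1000


@dataclass
class LikelihoodSurface:
    n1_grid: np.ndarray
    t1_grid: np.ndarray
    loglik: np.ndarray  # (len(n1_grid), len(t1_grid))
    R: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loglik, index=self.n1_grid,
                            columns=self.t1_grid)


def default_grids(n0: float, n_points: int = 5):
    """Geometric grids: N1 in N0*[0.02, 1], T1 in 4*N0*[0.005, 0.25]."""
    n1 = n0 * np.geomspace(0.02, 1.0, n_points)
    t1 = 4.0 * n0 * np.geomspace(0.005, 0.25, n_points)
    return n1, t1


def simulate_segregating_sites(n: int, theta_locus: float, R: int,
                               rng) -> np.ndarray:
    """S for R constant-size loci: S ~ Poisson(sum_k Exp(theta/(k-1)))."""
    k = np.arange(2, n + 1)
    branch = rng.exponential(theta_locus / (k - 1), size=(R, n - 1))
    return rng.poisson(branch.sum(axis=1))


def estimate_n0(locus_summaries, n_wild: int, mu: float,
                n0_grid, R: int = 2000, seed=None,
                length: int | None = None):
    """1-D composite log-likelihood curve over the N0 grid, plus the MLE."""
    n0_grid = np.asarray(n0_grid, dtype=float)
    if n0_grid.size == 0:
        raise ValueError("empty N0 grid")
    obs = np.array([ls.s_wild for ls in locus_summaries])
    if len(obs) < 50:
        log.warning("only %d loci; N0 estimate will be noisy", len(obs))
    L = length or locus_summaries[0].length
    rng = np.random.default_rng(seed)
    curve = []
    for n0 in n0_grid:
        theta = 4.0 * n0 * mu * L
        sims = simulate_segregating_sites(n_wild, theta, R, rng)
        support = int(max(sims.max(initial=0), obs.max(initial=0))) + 1
        counts = np.bincount(sims, minlength=support)
        pmf = (counts + 1.0) / (R + support)
        curve.append(np.log(pmf[obs]).sum())
    curve = np.asarray(curve)
    mle = float(n0_grid[int(np.argmax(curve))])
    return pd.DataFrame({"N0": n0_grid, "loglik": curve}), mle


def _joint_segregating_counts(n_w: int, n_c: int, n0: float, n1: float,
                              t1: float, mu_locus: float, R: int, rng):
    """Joint (S_wild, S_cult) under the two-population model, R replicates.

    Event-driven coalescent without recombination; branch lengths are
    partitioned into wild-only-, cultivated-only- and jointly-segregating
    classes so the two counts share mutations on shared branches.
    """
    s_w = np.empty(R, dtype=np.int64)
    s_c = np.empty(R, dtype=np.int64)
    for r in range(R):
        lw = lc = lb = 0.0
        # lineage = (wild descendants, cultivated descendants, population)
        lins = [(1, 0, 0)] * n_w + [(0, 1, 1)] * n_c
        t = 0.0
        merged = False
        while len(lins) > 1:
            active_w = [i for i, x in enumerate(lins) if 0 < x[0] < n_w
                        or 0 < x[1] < n_c]
            if not active_w:
                break
            k0 = sum(1 for x in lins if x[2] == 0)
            k1 = len(lins) - k0
            r0 = k0 * (k0 - 1) / (4.0 * n0)
            r1 = 0.0 if merged else k1 * (k1 - 1) / (4.0 * n1)
            tot = r0 + r1
            dt = rng.exponential(1.0 / tot) if tot > 0 else np.inf
            if not merged and t + dt >= t1:
                dt = t1 - t
                event = None
            else:
                event = 0 if rng.random() * tot < r0 else 1
            for w, c, _ in lins:
                seg_w = 0 < w < n_w
                seg_c = 0 < c < n_c
                if seg_w and seg_c:
                    lb += dt
                elif seg_w:
                    lw += dt
                elif seg_c:
                    lc += dt
            t += dt
            if event is None:
                merged = True
                lins = [(w, c, 0) for w, c, _ in lins]
                continue
            idx = [i for i, x in enumerate(lins) if x[2] == event]
            i, j = rng.choice(len(idx), size=2, replace=False)
            a = lins[idx[i]]
            b = lins[idx[j]]
            for ix in sorted((idx[i], idx[j]), reverse=True):
                lins.pop(ix)
            lins.append((a[0] + b[0], a[1] + b[1], event))
        nw_only = rng.poisson(mu_locus * lw)
        nc_only = rng.poisson(mu_locus * lc)
        nboth = rng.poisson(mu_locus * lb)
        s_w[r] = nw_only + nboth
        s_c[r] = nc_only + nboth
    return s_w, s_c


def bottleneck_likelihood_surface(locus_summaries, n_wild: int, n_cult: int,
                                  n0: float, mu: float, n1_grid, t1_grid,
                                  R: int = 2000, seed=None,
                                  length: int | None = None
                                  ) -> LikelihoodSurface:
    """Composite log-likelihood of (S_cult | S_wild) over the (N1, T1) grid.

    Per cell, R two-population loci are simulated and binned into an
    empirical conditional with add-one smoothing; observed S_wild strata
    never seen in simulation fall back to the nearest simulated stratum
    (logged)."""
    n1_grid = np.asarray(n1_grid, dtype=float)
    t1_grid = np.asarray(t1_grid, dtype=float)
    obs_w = np.array([ls.s_wild for ls in locus_summaries])
    obs_c = np.array([ls.s_cult for ls in locus_summaries])
    L = length or locus_summaries[0].length
    mu_locus = mu * L
    master = np.random.default_rng(seed)
    loglik = np.full((n1_grid.size, t1_grid.size), np.nan)
    for i, n1 in enumerate(n1_grid):
        for j, t1 in enumerate(t1_grid):
            rng = np.random.default_rng(master.integers(2**31))
            try:
                s_w, s_c = _joint_segregating_counts(
                    n_wild, n_cult, n0, n1, t1, mu_locus, R, rng)
            except Exception:  # cell flagged, not silently dropped
                log.exception("simulation failed at N1=%g T1=%g", n1, t1)
                continue
            loglik[i, j] = _conditional_loglik(s_w, s_c, obs_w, obs_c)
    return LikelihoodSurface(n1_grid, t1_grid, loglik, R, seed)


def _conditional_loglik(s_w, s_c, obs_w, obs_c) -> float:
    strata = np.unique(s_w)
    tables = {int(sw): s_c[s_w == sw] for sw in strata}
    total = 0.0
    n_fallback = 0
    for ow, oc in zip(obs_w, obs_c):
        if int(ow) in tables:
            vals = tables[int(ow)]
        else:
            n_fallback += 1
            nearest = int(strata[np.argmin(np.abs(strata - ow))])
            vals = tables[nearest]
        support = int(max(vals.max(initial=0), oc)) + 1
        count = int((vals == oc).sum())
        total += np.log((count + 1.0) / (len(vals) + support))
    if n_fallback:
        log.info("conditional likelihood: %d loci used nearest S_wild "
                 "stratum", n_fallback)
    return total


def bottleneck_mle(surface: LikelihoodSurface):
    """Argmax cell; ties break toward the least extreme bottleneck
    (largest N1, then smallest T1).  Returns ((N1*, T1*), profiles)."""
    ll = surface.loglik
    if np.all(np.isnan(ll)):
        raise ValueError("likelihood surface entirely flagged")
    best = np.nanmax(ll)
    ties = np.argwhere(np.isclose(ll, best, rtol=0, atol=0))
    # prefer largest N1 (row index), then smallest T1 (column index)
    ties = sorted(map(tuple, ties), key=lambda ij: (-ij[0], ij[1]))
    i, j = ties[0]
    profiles = {
        "N1": pd.DataFrame({"N1": surface.n1_grid,
                            "loglik": np.nanmax(ll, axis=1)}),
        "T1": pd.DataFrame({"T1": surface.t1_grid,
                            "loglik": np.nanmax(ll, axis=0)}),
    }
    return (float(surface.n1_grid[i]), float(surface.t1_grid[j])), profiles


def summarize_loci(panel, annotation, popmap, wild_group: str = "rufipogon",
                   cult_group: str = "sativa",
                   n_sites: int = 1000) -> list[LocusSummary]:
    """Per-gene (S_wild, S_cult) over the first n_sites synonymous sites."""
    from . import stats

    out = []
    wild = stats.per_gene_synonymous_pi(panel, annotation, popmap,
                                        wild_group, n_sites)
    cult = stats.per_gene_synonymous_pi(panel, annotation, popmap,
                                        cult_group, n_sites)
    merged = wild.merge(cult, on="gene_id", suffixes=("_w", "_c"))
    for _, row in merged.iterrows():
        if row["included_w"] and row["included_c"]:
            out.append(LocusSummary(row["gene_id"],
                                    int(row["n_segregating_w"]),
                                    int(row["n_segregating_c"]), n_sites))
    return out
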