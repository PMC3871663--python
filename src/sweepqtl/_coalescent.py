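"""Structured-coalescent simulation engine with recombination (Hudson-style ARG).

Backward-in-time simulation of a two-population sample: the cultivated
population has diploid effective size ``Ne[1]`` from the present back to the
founding time ``T1`` (generations), at which point its lineages join the wild
population of constant size ``Ne[0]``.  Infinite-sites mutations fall on
ancestral material at rate ``mu`` per bp per generation; recombination acts at
per-population effective rates ``rec[p]`` per bp per generation (selfing
scaling is applied by the caller).

Each lineage carries a list of ancestral segments ``(left, right, mask)`` on
the continuous interval ``[0, L)``; ``mask`` is a bitmask over sample indices
recording which samples descend from the lineage at that stretch of sequence.
Segments whose mask covers the full sample have found their MRCA and are
dropped, so the simulation terminates when no ancestral material remains.

A completed selective sweep in the cultivated population is modelled by the
star approximation: at the fixation time every cultivated lineage draws an
exponential escape distance on each side of the sweep site (mean ``lam`` bp);
material inside the non-escaping interval coalesces instantaneously into a
single lineage, material outside escapes the sweep.
"""

from __future__ import annotations

import math
from bisect import bisect_left


def _merge(a, b, full):
    """Union of two ancestry segment lists, OR-ing descendant masks.

    Segments that reach the full sample mask are dropped (MRCA found).
    """
    pts = sorted({p for seg in a for p in (seg[0], seg[1])}
                 | {p for seg in b for p in (seg[0], seg[1])})
    out = []
    ia = ib = 0
    na, nb = len(a), len(b)
    for i in range(len(pts) - 1):
        lo, hi = pts[i], pts[i + 1]
        while ia < na and a[ia][1] <= lo:
            ia += 1
        while ib < nb and b[ib][1] <= lo:
            ib += 1
        m = 0
        if ia < na and a[ia][0] <= lo:
            m |= a[ia][2]
        if ib < nb and b[ib][0] <= lo:
            m |= b[ib][2]
        if m and m != full:
            if out and out[-1][1] == lo and out[-1][2] == m:
                out[-1] = (out[-1][0], hi, m)
            else:
                out.append((lo, hi, m))
    return out


def _split(segs, x):
    """Split a segment list at breakpoint ``x`` into (left, right) lists."""
    left, right = [], []
    for l, r, m in segs:
        if r <= x:
            left.append((l, r, m))
        elif l >= x:
            right.append((l, r, m))
        else:
            left.append((l, x, m))
            right.append((x, r, m))
    return left, right


def _lineage(segs, pop):
    """[segments, population, breakable span, ancestral length]."""
    span = segs[-1][1] - segs[0][0]
    alen = 0.0
    for l, r, _ in segs:
        alen += r - l
    return [segs, pop, span, alen]


def _place_mutations(muts, lineages, alen_total, n_mut, rng):
    if n_mut == 0:
        return
    cum = []
    acc = 0.0
    for lin in lineages:
        acc += lin[3]
        cum.append(acc)
    for _ in range(n_mut):
        x = rng.random() * acc
        li = bisect_left(cum, x)
        if li >= len(lineages):
            li = len(lineages) - 1
        segs = lineages[li][0]
        y = rng.random() * lineages[li][3]
        for l, r, m in segs:
            y -= r - l
            if y <= 0.0:
                muts.append((r + y, m))
                break


def simulate_arg(n0, n1, L, Ne, rec, mu, T1, sweep, rng):
    """Run the ARG back in time; return mutations as (position, mask) pairs.

    Parameters
    ----------
    n0, n1 : int
        Haploid sample sizes in the wild (pop 0) and cultivated (pop 1)
        populations.  With ``T1 is None`` all samples start in pop 0.
    L : float
        Locus length in bp.
    Ne, rec : sequence of two floats
        Per-population effective diploid sizes and effective per-bp
        recombination rates.
    mu : float
        Mutation rate per bp per generation.
    T1 : float or None
        Population-merge time in generations (None = single population).
    sweep : None or (pos, t_fix, lam)
        Star-approximation sweep in pop 1, position in locus coordinates
        (may lie outside [0, L)).
    rng : numpy.random.Generator
    """
    n = n0 + n1
    if n < 2:
        return []
    full = (1 << n) - 1
    lineages = []
    single_pop = T1 is None
    for i in range(n0):
        lineages.append(_lineage([(0.0, float(L), 1 << i)], 0))
    for j in range(n1):
        lineages.append(_lineage([(0.0, float(L), 1 << (n0 + j))],
                                 0 if single_pop else 1))

    pending = []  # (time, kind); sweep sorts before merge at equal times
    if sweep is not None and n1 > 0 and not single_pop:
        pos, t_fix, lam = sweep
        pending.append((float(t_fix), 0, (pos, lam)))
    if not single_pop:
        pending.append((float(T1), 1, None))
    pending.sort(key=lambda e: (e[0], e[1]))

    muts = []
    t = 0.0
    while lineages:
        k = [0, 0]
        span = [0.0, 0.0]
        alen = 0.0
        for lin in lineages:
            k[lin[1]] += 1
            span[lin[1]] += lin[2]
            alen += lin[3]
        crate = [k[p] * (k[p] - 1) / (4.0 * Ne[p]) for p in (0, 1)]
        rrate = [rec[p] * span[p] for p in (0, 1)]
        tot = crate[0] + crate[1] + rrate[0] + rrate[1]
        dt = rng.exponential(1.0 / tot) if tot > 0.0 else math.inf
        if pending and t + dt >= pending[0][0]:
            bt, kind, payload = pending.pop(0)
            n_mut = rng.poisson(mu * (bt - t) * alen) if alen > 0 else 0
            _place_mutations(muts, lineages, alen, n_mut, rng)
            t = bt
            if kind == 1:  # populations merge into the wild ancestor
                for lin in lineages:
                    lin[1] = 0
            else:  # star-approximation sweep in pop 1
                pos, lam = payload
                lineages = _apply_sweep(lineages, pos, lam, full, rng)
            continue
        n_mut = rng.poisson(mu * dt * alen) if alen > 0 else 0
        _place_mutations(muts, lineages, alen, n_mut, rng)
        t += dt
        u = rng.random() * tot
        if u < crate[0] + crate[1]:
            p = 0 if u < crate[0] else 1
            _coalesce(lineages, p, full, rng)
        else:
            u -= crate[0] + crate[1]
            p = 0 if u < rrate[0] else 1
            _recombine(lineages, p, span[p], rng)
    return muts


def _coalesce(lineages, p, full, rng):
    idx = [i for i, lin in enumerate(lineages) if lin[1] == p]
    i, j = rng.choice(len(idx), size=2, replace=False)
    a, b = lineages[idx[i]], lineages[idx[j]]
    merged = _merge(a[0], b[0], full)
    for ix in sorted((idx[i], idx[j]), reverse=True):
        lineages.pop(ix)
    if merged:
        lineages.append(_lineage(merged, p))


def _recombine(lineages, p, span_total, rng):
    x = rng.random() * span_total
    for i, lin in enumerate(lineages):
        if lin[1] != p:
            continue
        if x < lin[2]:
            bp = lin[0][0][0] + x
            left, right = _split(lin[0], bp)
            if left and right:
                lineages[i] = _lineage(left, p)
                lineages.append(_lineage(right, p))
            return
        x -= lin[2]


def _apply_sweep(lineages, pos, lam, full, rng):
    """All non-escaping cultivated material coalesces into one star lineage."""
    survivors = []
    star = None
    for lin in lineages:
        if lin[1] != 1:
            survivors.append(lin)
            continue
        lo = pos - rng.exponential(lam)
        hi = pos + rng.exponential(lam)
        inner, right = _split(lin[0], hi)
        left, swept = _split(inner, lo)
        escaped = left + right
        if escaped:
            survivors.append(_lineage(escaped, 1))
        if swept:
            star = swept if star is None else _merge(star, swept, full)
    if star:
        survivors.append(_lineage(star, 1))
    return survivors
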