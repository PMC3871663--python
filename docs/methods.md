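# Methods

`sweepqtl` re-implements, as a tested pipeline on synthetic data, a
population-genomic procedure for locating domestication targets in rice:
estimate the domestication bottleneck from genome-wide diversity, build a
simulation null of windowed diversity ratios under that bottleneck, call
candidate sweep regions where the cultivated/wild ratio is in the extreme
lower tail by two measures, scan for inter-group differentiation with
F\_ST, co-localize candidate regions with mapped QTLs, and screen genes in
the regions for variants fixed in the cultivated group.

## Demographic model

The model is a two-population split with a bottleneck: the cultivated
population has constant diploid effective size `N1` from the present back
to the founding time `T1` (generations), at which point its lineages join
the wild population of constant size `N0`.  Partial self-fertilization at
rate `s` enters through the equilibrium inbreeding coefficient
`F = s / (2 - s)`: each population behaves as a haploid-lineage coalescent
with effective size `N / (1 + F)` and effective recombination rate
`rec * (1 - F)` per bp per generation.  Lineages are haploid throughout,
matching panels of inbred accessions whose genomes are essentially
homozygous.  A recovery/expansion phase after founding is deliberately not
modelled; the three parameters `(N0, N1, T1)` are exactly the quantities
the inference module estimates.

Desk-scale defaults (`default_model()`): `N0 = 10,000`, `N1 = 1,500`,
`T1 = 1,000` generations, `mu = 6.5e-9` and `rec = 4e-8` per bp per
generation, selfing 0.90 (wild) and 0.95 (cultivated).  These were chosen
so that (a) the neutral cultivated/wild diversity ratio is ~0.60, the
genome-wide reduction cultivated rice shows against *O. rufipogon*, and
(b) the founding time is short relative to the wild coalescent time scale
(`T1 / 2·Ne_wild ≈ 0.09`, as in rice, where domestication is recent
relative to the wild species' effective size), so completed sweeps leave
troughs clearly below the bottleneck background.  Absolute sizes are scaled
down from the rice values (N0 of order 10^5) to keep simulation tractable;
all rank-based and ratio-based statistics are invariant to this scaling,
absolute per-bp diversity is not.

## The coalescent engine

`simdata` contains a Hudson-style ancestral-recombination-graph simulator:
lineages carry lists of ancestral segments with descendant-sample bitmasks,
coalescence merges segment lists (segments reaching the full sample mask
have found their MRCA and are dropped), recombination splits a lineage at a
point uniform on its breakable span, and infinite-sites mutations fall on
ancestral material in proportion to exposure, at continuous positions
rounded to integer bp (collisions re-drawn).  msprime is used in the test
suite as an independent oracle for the site-frequency spectrum and mean
diversity on matched parameters; it is never the implementation.

A completed selective sweep is the star approximation: at the fixation
time `t_fix` (default: the founding time) every cultivated lineage draws an
exponential escape distance with mean `lam` on each side of the sweep
position; material inside the non-escaping interval coalesces
instantaneously into a single lineage, material outside escapes.  This
reproduces the per-site escape probability `1 - exp(-d/lam)` and gives
pairwise coalescence times ~`t_fix` at the sweep center (per-site
cultivated diversity `~2*mu*t_fix`).  No selection coefficients are
modelled; the sweep is specified purely by its diversity footprint scale
`lam`.

## Genome synthesis and stitching granularity

`synthesize_genome` builds a multi-chromosome panel by stitching
independently simulated loci (`locus_size`, default 5 kb), a random
codon-structured reference (genes with two CDS exons, UTRs and an intron,
so synonymous/replacement/frameshift calls are decidable), a GRAMENE-style
QTL table in which some QTLs are deliberately centred near planted sweeps,
missing calls with per-site quality/depth annotations, and truth tables.

The stitching granularity is a deliberate modelling choice.  At the
desk-scale `N0` the within-locus scaled recombination rate is ~30-fold
smaller than in real wild rice, where `rho` per 10 kb is ≈15 and marginal
genealogies decorrelate within a few kb.  Stitching at 5 kb restores the
genealogical turnover per 500-kb window (~100 quasi-independent trees) that
the real panel has; simulating each 500-kb window as one fully linked ARG
would overstate window-to-window variance by an order of magnitude and make
both the null and the sweep footprints erratic in a way real data are not.
The cost is that synthetic LD decays to baseline within ~5-10 kb rather
than the ~100 kb seen in rice; the LD module is therefore exercised on
single fully-linked loci, not on stitched genomes.  The simulation null
(`build_null_distribution`) stitches its window replicates with the same
`locus_size` as the genome, so observed and null windows are produced by
the identical neutral process.  A fast independent-tile mode
(`engine="tile"`) exists for quick experiments and is flagged as
understating window-ratio variance further.

## Estimators

Per-site diversity is the mean pairwise difference among called alleles,
`d(n-d) / C(n,2)`; Watterson's estimator uses per-site called sample sizes,
`sum_i 1/a_{n_i - 1}` over segregating sites.  Window values divide the
summed per-site quantities by the number of callable sites in the window —
by default the window span in bp, with a site-mask/callable-count override.
Window scans default to all panel sites rather than a gene-region mask: the
gene restriction in resequencing studies guards against paralogous
mismapping in repeat regions, which synthetic genomes do not have; the mask
option (`site_mask="genes"`) reproduces the restricted behaviour.

F\_ST is the Hudson estimator in ratio-of-sums form,
`1 - sum(within) / sum(between)`, with within = the average of the two
per-population mean pairwise differences and between = `p_a(1-p_b) +
p_b(1-p_a)`.  Because the pairwise within is the unbiased heterozygosity,
sites where both samples show identical frequencies score slightly negative
(order `-1/(2n)`); negative window values are retained in tracks but never
rank as differentiation peaks.  Per-gene synonymous diversity takes, per
gene, the first 1000 synonymous-class sites (fourfold-degenerate third
codon positions) in transcript order from the translation start; genes with
fewer are excluded.

LD decay computes `r^2 = D^2 / (p_1 q_1 p_2 q_2)` for intra-chromosomal
pairs on samples called at both sites, optionally after per-pair random
subsampling to a common size (the device used to equalize sample sizes
across populations), averaged in 2-kb distance bins up to 1 Mb.

## Bottleneck inference

The data are per-locus segregating-site counts on fixed-length loci (1000
synonymous sites).  `estimate_n0` simulates, for each grid value, the
distribution of S under a constant-size coalescent with `theta = 4 N0 mu`
per site (branch lengths drawn exactly via exponentials, S Poisson), forms
an add-one-smoothed probability mass, and sums log-probabilities over loci.
`bottleneck_likelihood_surface` fixes N0 and simulates, per `(N1, T1)`
cell, joint `(S_wild, S_cult)` counts — shared branches contribute shared
mutations, so the two counts are properly dependent — and scores loci by
the empirical conditional `P(S_cult | S_wild)` with add-one smoothing;
observed wild strata never simulated fall back to the nearest stratum.
Loci are non-recombining internally and free between (composite
likelihood).  Ties at the maximum break toward the mildest bottleneck
(largest N1, then smallest T1).  The N1 x T1 surface shows the expected
severity ridge (a smaller N1 with a shorter T1 mimics a larger N1 with a
longer T1), which is why recovery is asserted to within one grid cell, not
to the exact cell.  Default grids are geometric: N1 over `N0*[0.02, 1]`,
T1 over `4*N0*[0.005, 0.25]`.

## The sweep scan

The null is `R` window-sized neutral replicates of `pi_cult/pi_wild` and
`theta_cult/theta_wild` under the (estimated or true) bottleneck model;
replicates with zero wild diversity are re-drawn and counted.  Each
observed window gets `p = (#{null <= observed} + 1) / (R + 1)` and
`logP = -log10 p`, so `logP <= log10(R+1)` and no window has p = 0.

Region calling ranks windows per measure over *distinct peaks*: the
best-scoring window is selected, windows overlapping it are shadowed, and
selection continues to the top K (default 15).  On a 20-kb-step grid the
~45 overlapping windows covering one trough would otherwise exhaust all K
slots on a single region, which is incompatible with the procedure's intent
of returning on the order of ten distinct regions from a top-15 rule.
Ties break toward the lower observed ratio, then the leftmost window;
windows with logP = 0 (observed ratio at or above every null replicate)
never rank.  A peak qualifies when it overlaps a top-K peak of the other
measure; qualifying windows that overlap or abut merge into regions
labelled S01, S02, ... in genomic order.

The F\_ST scan reuses the window machinery with the ratio-of-sums Hudson
estimator per window and reports top-K peaks descriptively; a
label-permutation quantile is available as an empirical significance bar
and is an addition of this package, flagged as such where used.

## QTL co-localization and the fixed-variant screen

A QTL's position is the midpoint of its mapped interval; QTLs spanning
more than 5 Mb are discarded as too imprecise, and a QTL maps to a region
when its midpoint lies within the region padded by 2 Mb on each side.
Trait categories matching keyword lists for shattering, awn, dormancy and
grain quality are counted separately per region.

The screen visits every panel variant inside a candidate region and
reports it when: called-sample minima hold (>= 6 wild, >= 12 cultivated;
>= 6 when screening an indica-specific region against indica), all called
cultivated accessions carry one identical allele (the allele may equal the
reference), the per-site Hudson F\_ST against the wild group is >= 0.7,
and the effect class is replacement, frameshift, upstream (within 200 bp
5' of an annotated transcription start site) or downstream (within 100 bp
3' of it), strand-aware.  Coding SNPs are translated ref-vs-alt with the
standard code; coding indels are frameshift unless their length is a
multiple of three.  Variants in overlapping regions are reported once.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; VCF/GFF3 conversion happens
only at I/O.  Heterozygous or half-called diploid genotypes become missing
(hets in inbred accessions are treated as artifacts), multi-allelic sites
are dropped with a logged count, and SNP filters keep `QUAL >= 100` and
`3 <= DP < 100`, counting each removal under the first threshold it fails.
Sites monomorphic after degradation are removed to keep every panel site
segregating.  Terminal windows truncated by the chromosome end are emitted
and flagged, and excluded from peak ranking by default.  Undefined values
(zero callable sites, zero wild diversity, zero between-population
diversity) propagate as NaN rather than zero.

## Synthetic-data scope

The generator emulates: near-homozygous accessions from a two-population
bottleneck coalescent with partial selfing, completed sweeps with a
realistic footprint scale, missing calls with quality/depth annotations on
which the SNP filters act, codon-structured genes, and QTLs of realistic
(0.5-8 Mb) mapped spans.  It does not emulate: population structure within
the cultivated group (indica/japonica labels are assigned, not simulated —
differentiation scans are validated on planted blocks instead), repetitive
sequence and mismapping, sequencing-error SNPs, reference bias (the
reference carries the ancestral allele everywhere), or realistic LD beyond
the stitching granularity.  Passing tests therefore validate the
statistical machinery under the stated model, not robustness to artifacts
real resequencing data contain.

## Problem sizes

The validation experiments run at: 2,000 loci for estimator calibration
and the split-model F\_ST check; R = 5,000 null replicates and 1,000
independent observed windows for logP calibration; a 30-Mb, 3-chromosome
genome with three planted sweeps (lambda = 200 kb) for recall; 200 loci and
R = 2,000 per grid cell on 5x5 geometric grids for demographic recovery.
These sizes keep the full validation run within tens of minutes on one
core while leaving Monte-Carlo error well inside the asserted tolerances.
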