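"""Synthetic study data: coalescent panels under a domestication bottleneck.

The demographic model is a two-population split: the cultivated population
has constant diploid size N1 from the present back to the founding time T1
(generations), when it merges into the wild population of constant size N0.
Partial selfing at rate s enters through the equilibrium inbreeding
coefficient F = s / (2 - s): effective size N / (1 + F) and effective
recombination rate rec * (1 - F) per population; lineages are treated as
haploid thereafter, matching panels of inbred accessions.

Completed selective sweeps in the cultivated population are planted with a
star approximation: at the fixation time, cultivated-lineage material at
distance d from the sweep site escapes with probability 1 - exp(-d / lam)
and everything that does not escape coalesces instantaneously.

``synthesize_genome`` stitches independently simulated loci into a
multi-chromosome panel with a codon-structured random reference, gene
annotation, a GRAMENE-style QTL table (some QTLs deliberately placed over
planted sweeps), missing calls with quality/depth annotations, and truth
tables for every planted feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._coalescent import simulate_arg
from . import annotate as _annotate
from . import io_formats as iof

log = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


@dataclass(frozen=True)
class SweepSpec:
    """A completed sweep planted in the cultivated population."""

    chrom: str
    pos: int
    lam: float
    t_fix: float | None = None  # defaults to the founding time T1
    target: str = "cult"

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("sweep lam must be > 0")


@dataclass(frozen=True)
class DemographicModel:
    """Two-population split-with-bottleneck model with partial selfing."""

    N0: float
    N1: float
    T1: float | None
    mu: float = 6.5e-9
    rec: float = 4e-8
    s_wild: float = 0.9
    s_cult: float = 0.95
    sweeps: tuple[SweepSpec, ...] = ()

    def __post_init__(self):
        if not (np.isfinite(self.N0) and self.N0 > 0):
            raise ValueError("N0 must be positive and finite")
        if not (np.isfinite(self.N1) and self.N1 > 0):
            raise ValueError("N1 must be positive and finite")
        if self.T1 is not None and not (np.isfinite(self.T1) and self.T1 > 0):
            raise ValueError("T1 must be positive (or None to disable split)")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be >= 0")
        for s in (self.s_wild, self.s_cult):
            if not 0 <= s < 1:
                raise ValueError("selfing rates must lie in [0, 1)")
        for sw in self.sweeps:
            t = self.T1 if sw.t_fix is None else sw.t_fix
            if self.T1 is not None and not 0 < t <= self.T1:
                raise ValueError("sweep t_fix must satisfy 0 < t_fix <= T1")

    @staticmethod
    def _inbreeding(s: float) -> float:
        return s / (2.0 - s)

    @property
    def F_wild(self) -> float:
        return self._inbreeding(self.s_wild)

    @property
    def F_cult(self) -> float:
        return self._inbreeding(self.s_cult)

    @property
    def Ne_wild(self) -> float:
        return self.N0 / (1.0 + self.F_wild)

    @property
    def Ne_cult(self) -> float:
        return self.N1 / (1.0 + self.F_cult)

    @property
    def rec_wild(self) -> float:
        return self.rec * (1.0 - self.F_wild)

    @property
    def rec_cult(self) -> float:
        return self.rec * (1.0 - self.F_cult)


def default_model(**overrides) -> DemographicModel:
    """Desk-scale study conditions.

    Chosen so that (a) the neutral cultivated/wild diversity ratio is ~0.6,
    the genome-wide reduction domesticated rice shows against its wild
    progenitor, and (b) the founding time is short relative to the wild
    coalescent time scale (T1 / 2*Ne_wild ~ 0.1), as in rice, so completed
    sweeps leave deep troughs against the bottleneck background.
    """
    params = dict(N0=10_000.0, N1=1_500.0, T1=1_000.0)
    params.update(overrides)
    return DemographicModel(**params)


@dataclass
class HaplotypePanel:
    """Samples x segregating sites over one locus, haploid-coded."""

    samples: list[str]
    populations: list[str]
    L: int
    positions: np.ndarray
    alleles: np.ndarray
    qual: np.ndarray | None = None
    depth: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def rows(self, population: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.populations)
                         if p == population], dtype=int)


def simulate_locus(model: DemographicModel, n_wild: int, n_cult: int, L: int,
                   sweep: SweepSpec | None = None, seed=None,
                   engine: str = "arg", tile: int = 1000,
                   origin: int = 0) -> HaplotypePanel:
    """Simulate one locus of length ``L`` bp under the structured coalescent.

    ``sweep.pos`` is interpreted in the same coordinate system as the locus
    shifted by ``origin`` (so a genome-level sweep can act at a distance on
    a locus that does not contain it).  ``engine='tile'`` simulates
    independent ``tile``-bp pieces without linkage (fast, understates
    window-ratio variance); the default ARG engine is exact.
    """
    if L <= 0:
        raise ValueError("locus length L must be > 0")
    if n_wild < 0 or n_cult < 0 or n_wild + n_cult < 2:
        raise ValueError("need n_wild + n_cult >= 2 samples")
    if model.T1 is None and n_cult > 0 and sweep is not None:
        raise ValueError("sweeps require a two-population model")
    rng = np.random.default_rng(seed)
    if engine == "tile":
        panels = []
        for t0 in range(0, L, tile):
            sub = simulate_locus(replace(model, rec=0.0), n_wild, n_cult,
                                 min(tile, L - t0), sweep=sweep,
                                 seed=rng.integers(2**31),
                                 origin=origin + t0)
            panels.append((t0, sub))
        pos = np.concatenate([p.positions + t0 for t0, p in panels])
        alle = np.concatenate([p.alleles for _, p in panels], axis=1)
        first = panels[0][1]
        return HaplotypePanel(first.samples, first.populations, L,
                              pos, alle)
    if engine != "arg":
        raise ValueError(f"unknown engine {engine!r}")
    sw = None
    if sweep is not None:
        t_fix = model.T1 if sweep.t_fix is None else sweep.t_fix
        sw = (float(sweep.pos - origin), float(t_fix), float(sweep.lam))
    muts = simulate_arg(
        n_wild, n_cult, float(L),
        Ne=(model.Ne_wild, model.Ne_cult),
        rec=(model.rec_wild, model.rec_cult),
        mu=model.mu, T1=model.T1, sweep=sw, rng=rng)
    n = n_wild + n_cult
    used: set[int] = set()
    records = []
    for pos_f, mask in muts:
        p = int(pos_f)
        while p in used:  # infinite-sites collision after rounding
            p = int(rng.integers(0, L))
        used.add(p)
        records.append((p, mask))
    records.sort()
    positions = np.array([p for p, _ in records], dtype=np.int64)
    if n <= 64:
        masks = np.array([m for _, m in records], dtype=np.uint64)
        shifts = np.arange(n, dtype=np.uint64)[:, None]
        alleles = ((masks[None, :] >> shifts) & np.uint64(1)).astype(np.int8)
    else:
        alleles = np.zeros((n, len(records)), dtype=np.int8)
        for j, (_, mask) in enumerate(records):
            for i in range(n):
                if mask >> i & 1:
                    alleles[i, j] = 1
    samples = ([f"W{i + 1:02d}" for i in range(n_wild)]
               + [f"C{i + 1:02d}" for i in range(n_cult)])
    populations = ["wild"] * n_wild + ["cult"] * n_cult
    return HaplotypePanel(samples, populations, L, positions, alleles)


def _draw(spec, size, rng) -> np.ndarray:
    """Draw ``size`` values from a small distribution spec dict."""
    dist = spec.get("dist", "constant")
    if dist == "gamma":
        return rng.gamma(spec["shape"], spec["scale"], size)
    if dist == "poisson":
        return rng.poisson(spec["lam"], size).astype(float)
    if dist == "normal":
        return rng.normal(spec["mean"], spec["sd"], size)
    if dist == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if dist == "constant":
        return np.full(size, float(spec.get("value", 0.0)))
    raise ValueError(f"unknown distribution {dist!r}")


def degrade_panel(panel: HaplotypePanel, missing_rate: float,
                  qual_model: dict | None = None,
                  depth_model: dict | None = None,
                  seed=None) -> HaplotypePanel:
    """Mask calls missing at ``missing_rate`` and annotate per-site
    quality/depth draws; sites monomorphic after degradation are dropped."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    qual_model = qual_model or {"dist": "gamma", "shape": 4.0, "scale": 75.0}
    depth_model = depth_model or {"dist": "poisson", "lam": 20.0}
    alleles = panel.alleles.copy()
    if missing_rate > 0 and alleles.size:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = iof.MISSING
    qual = np.round(_draw(qual_model, panel.n_sites, rng), 2)
    depth = np.round(_draw(depth_model, panel.n_sites, rng)).astype(float)
    derived = (alleles == 1).sum(axis=0)
    called = (alleles >= 0).sum(axis=0)
    seg = (derived > 0) & (derived < called)
    n_drop = int((~seg).sum())
    if n_drop:
        log.info("degrade_panel: dropped %d sites monomorphic after "
                 "degradation", n_drop)
    return HaplotypePanel(panel.samples, panel.populations, panel.L,
                          panel.positions[seg], alleles[:, seg],
                          qual=qual[seg], depth=depth[seg])


# ---------------------------------------------------------------------------
# whole-genome synthesis


@dataclass
class GenomeConfig:
    """Layout of the synthetic study genome."""

    chrom_lengths: dict[str, int]
    n_wild: int = 10
    n_indica: int = 12
    n_temperate: int = 6
    n_tropical: int = 4
    locus_size: int = 5_000
    gene_spacing: int = 60_000
    cds_codons: int = 2100
    utr_len: int = 200
    intron_len: int = 300
    n_qtls_per_chrom: int = 30
    qtl_span_range: tuple[int, int] = (500_000, 8_000_000)
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.02
    qual_model: dict = field(default_factory=lambda: {
        "dist": "gamma", "shape": 4.0, "scale": 75.0})
    depth_model: dict = field(default_factory=lambda: {
        "dist": "poisson", "lam": 20.0})
    engine: str = "arg"

    @property
    def n_cult(self) -> int:
        return self.n_indica + self.n_temperate + self.n_tropical

    def __post_init__(self):
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not in "
                                 "genome")
            if not 0 <= sw.pos < self.chrom_lengths[sw.chrom]:
                raise ValueError(f"sweep position {sw.pos} outside "
                                 f"{sw.chrom}")


@dataclass
class GenomeTruth:
    """Everything planted into the synthetic genome."""

    model: DemographicModel
    sweeps: list[SweepSpec]
    planted_variants: pd.DataFrame


@dataclass
class DatasetBundle:
    panel: iof.GenotypePanel
    reference: dict[str, str]
    annotation: iof.GeneAnnotation
    qtls: pd.DataFrame
    popmap: iof.PopulationMap
    truth: GenomeTruth
    chrom_lengths: dict[str, int]


def _sample_names(config: GenomeConfig) -> tuple[list[str], dict[str, str]]:
    names, assignment = [], {}
    for i in range(config.n_wild):
        names.append(f"W{i + 1:02d}")
        assignment[names[-1]] = "rufipogon"
    for i in range(config.n_indica):
        names.append(f"IND{i + 1:02d}")
        assignment[names[-1]] = "indica"
    for i in range(config.n_temperate):
        names.append(f"TEJ{i + 1:02d}")
        assignment[names[-1]] = "japonica_temperate"
    for i in range(config.n_tropical):
        names.append(f"TRJ{i + 1:02d}")
        assignment[names[-1]] = "japonica_tropical"
    return names, assignment


def _build_genes(config: GenomeConfig, rng) -> iof.GeneAnnotation:
    genes = []
    cds_total = 3 * config.cds_codons
    cds1 = (cds_total // 2 // 3) * 3
    cds2 = cds_total - cds1
    for chrom, length in config.chrom_lengths.items():
        k = 0
        for g0 in range(2000, length, config.gene_spacing):
            start = g0 + int(rng.integers(0, 2000))
            u, i = config.utr_len, config.intron_len
            end = start + u + cds1 + i + cds2 + u
            if end >= length:
                break
            k += 1
            strand = "+" if k % 2 else "-"
            cds = [(start + u, start + u + cds1),
                   (start + u + cds1 + i, start + u + cds1 + i + cds2)]
            exons = [(start, start + u + cds1),
                     (start + u + cds1 + i, end)]
            genes.append(iof.Gene(f"{chrom}g{k:04d}", chrom, strand,
                                  start, end, cds, exons))
    return iof.GeneAnnotation(genes)


def _build_reference(config: GenomeConfig, annotation: iof.GeneAnnotation,
                     rng) -> dict[str, str]:
    reference = {}
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    for chrom, length in config.chrom_lengths.items():
        arr = base_codes[rng.integers(0, 4, size=length)]
        for gene in annotation.genes_on(chrom):
            n_codons = gene.cds_length // 3
            body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
            tx = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"
            tx_b = np.frombuffer(tx.encode(), dtype=np.uint8)
            pos = gene.cds_positions()
            arr[pos] = tx_b if gene.strand == "+" else comp[tx_b]
        reference[chrom] = arr.tobytes().decode("ascii")
    return reference


def synthesize_genome(config: GenomeConfig, model: DemographicModel,
                      seed=None) -> DatasetBundle:
    """Simulate the complete fake study dataset with planted sweeps."""
    rng = np.random.default_rng(seed)
    samples, assignment = _sample_names(config)
    popmap = iof.PopulationMap(assignment)
    annotation = _build_genes(config, rng)
    reference = _build_reference(config, annotation, rng)
    _annotate.attach_synonymous_sites(annotation, reference)

    frames, mats = [], []
    for chrom, length in config.chrom_lengths.items():
        sweeps_here = [s for s in config.sweeps if s.chrom == chrom]
        chrom_pos, chrom_alle = [], []
        for start in range(0, length, config.locus_size):
            lsz = min(config.locus_size, length - start)
            sweep = None
            if sweeps_here:
                sweep = min(sweeps_here,
                            key=lambda s: abs(s.pos - (start + lsz / 2)))
            sub = simulate_locus(model, config.n_wild, config.n_cult, lsz,
                                 sweep=sweep, seed=int(rng.integers(2**31)),
                                 engine=config.engine, origin=start)
            chrom_pos.append(sub.positions + start)
            chrom_alle.append(sub.alleles)
        positions = np.concatenate(chrom_pos)
        alleles = np.concatenate(chrom_alle, axis=1)
        hap = HaplotypePanel(samples, ["wild"] * config.n_wild
                             + ["cult"] * config.n_cult, length,
                             positions, alleles)
        hap = degrade_panel(hap, config.missing_rate, config.qual_model,
                            config.depth_model,
                            seed=int(rng.integers(2**31)))
        refseq = reference[chrom]
        refs = [refseq[p] for p in hap.positions]
        alts = []
        for r in refs:
            others = [b for b in "ACGT" if b != r]
            alts.append(others[int(rng.integers(3))])
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": hap.positions, "ref": refs, "alt": alts,
            "qual": hap.qual, "depth": hap.depth, "site_class": "unknown"}))
        mats.append(hap.alleles)
    sites = pd.concat(frames, ignore_index=True)
    alleles = np.concatenate(mats, axis=1)
    panel = iof.GenotypePanel(samples, alleles, sites)
    panel.sites["site_class"] = _annotate.classify_sites(panel, annotation,
                                                         reference)
    qtls = _build_qtls(config, rng)
    truth = GenomeTruth(model=model, sweeps=list(config.sweeps),
                        planted_variants=pd.DataFrame(columns=[
                            "chrom", "pos", "ref", "alt", "kind",
                            "gene_id", "expect_reported"]))
    return DatasetBundle(panel, reference, annotation, qtls, popmap,
                         truth, dict(config.chrom_lengths))


_QTL_CATEGORIES = ["yield", "vigor", "anatomy", "biochemical", "sterility",
                   "abiotic stress", "development"]
_QTL_TRAITS = ["plant height", "tiller number", "panicle length",
               "root thickness", "leaf width", "spikelet number"]
_HIGHLIGHT_TRAITS = [("seed shattering", "morphology"),
                     ("awn length", "morphology"),
                     ("seed dormancy", "development"),
                     ("grain quality", "quality")]


def _build_qtls(config: GenomeConfig, rng) -> pd.DataFrame:
    rows = []
    k = 0
    for chrom, length in config.chrom_lengths.items():
        for _ in range(config.n_qtls_per_chrom):
            k += 1
            span = int(rng.integers(*config.qtl_span_range))
            start = int(rng.integers(0, max(length - span, 1)))
            trait = _QTL_TRAITS[int(rng.integers(len(_QTL_TRAITS)))]
            cat = _QTL_CATEGORIES[int(rng.integers(len(_QTL_CATEGORIES)))]
            rows.append((f"AQ{k:04d}", trait, cat, chrom, start,
                         min(start + span, length)))
    for sweep in config.sweeps:
        length = config.chrom_lengths[sweep.chrom]
        for trait, cat in _HIGHLIGHT_TRAITS[:2]:
            k += 1
            span = int(rng.integers(1_000_000, 4_000_000))
            mid = sweep.pos + int(rng.integers(-500_000, 500_000))
            start = max(mid - span // 2, 0)
            rows.append((f"AQ{k:04d}", trait, cat, sweep.chrom, start,
                         min(start + span, length)))
    return pd.DataFrame(rows, columns=["id", "trait", "category", "chrom",
                                       "start", "end"])


# ---------------------------------------------------------------------------
# planted screen variants

_PLANT_KINDS = ("replacement", "frameshift", "upstream", "downstream",
                "near_fixed", "low_coverage")


def plant_screen_variants(bundle: DatasetBundle, chrom: str,
                          region: tuple[int, int], seed=None,
                          kinds=_PLANT_KINDS) -> DatasetBundle:
    """Plant known fixed (and decoy) variants into genes of one region.

    ``replacement``/``frameshift``/``upstream``/``downstream`` variants are
    fixed derived in all cultivated samples (wild all ancestral) and must
    be recovered by the screen; ``near_fixed`` (one cultivated sample still
    ancestral) and ``low_coverage`` (too few wild calls) must be rejected.
    """
    rng = np.random.default_rng(seed)
    genes = [g for g in bundle.annotation.genes_in(chrom, *region)
             if g.usable and g.start > region[0] + 300]
    if len(genes) < len(kinds):
        raise ValueError("not enough genes in region to plant variants")
    panel = bundle.panel
    popmap = bundle.popmap
    wi = popmap.indices_in(panel.samples, "wild")
    ci = popmap.indices_in(panel.samples, "cultivated")
    refseq = bundle.reference[chrom]
    used = set(panel.sites.loc[panel.sites["chrom"] == chrom, "pos"])
    new_rows, new_cols, truth_rows = [], [], []
    for kind, gene in zip(kinds, genes):
        pos, ref, alt = _pick_variant(kind, gene, refseq, bundle.annotation,
                                      used)
        used.add(pos)
        col = np.zeros(panel.n_samples, dtype=np.int8)
        col[ci] = 1
        expect = kind in ("replacement", "frameshift", "upstream",
                          "downstream")
        if kind == "near_fixed":
            col[ci[int(rng.integers(len(ci)))]] = 0
        if kind == "low_coverage":
            drop = rng.choice(wi, size=len(wi) - 5, replace=False)
            col[drop] = iof.MISSING
        new_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "qual": 500.0, "depth": 30.0,
                         "site_class": "unknown"})
        new_cols.append(col)
        truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref,
                           "alt": alt, "kind": kind,
                           "gene_id": gene.gene_id,
                           "expect_reported": expect})
    sites = pd.concat([panel.sites, pd.DataFrame(new_rows)],
                      ignore_index=True)
    alleles = np.concatenate([panel.alleles,
                              np.stack(new_cols, axis=1)], axis=1)
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy()))
    new_panel = iof.GenotypePanel(panel.samples, alleles[:, order],
                                  sites.iloc[order].reset_index(drop=True))
    truth = GenomeTruth(bundle.truth.model, bundle.truth.sweeps,
                        pd.concat([bundle.truth.planted_variants,
                                   pd.DataFrame(truth_rows)],
                                  ignore_index=True))
    return DatasetBundle(new_panel, bundle.reference, bundle.annotation,
                         bundle.qtls, bundle.popmap, truth,
                         bundle.chrom_lengths)


def _pick_variant(kind, gene, refseq, annotation, used):
    if kind in ("replacement", "near_fixed", "low_coverage"):
        for p in gene.cds_positions()[3:300]:
            p = int(p)
            if p in used:
                continue
            ref = refseq[p]
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect = _annotate.classify_variant_effect(
                    (gene.chrom, p, ref, alt), annotation,
                    {gene.chrom: refseq})
                if effect == "replacement":
                    return p, ref, alt
        raise RuntimeError("no replacement site found")
    if kind == "frameshift":
        for p in gene.cds_positions()[10:300]:
            p = int(p)
            if p in used or p + 2 in used:
                continue
            return p, refseq[p:p + 3], refseq[p]  # 2-bp deletion
        raise RuntimeError("no frameshift site found")
    if kind in ("upstream", "downstream"):
        t = gene.tss
        sign = 1 if gene.strand == "-" else -1
        offset = 150 if kind == "upstream" else -50
        p = t + sign * offset
        while p in used:
            p += sign
        ref = refseq[p]
        alt = next(b for b in "ACGT" if b != ref)
        return p, ref, alt
    raise ValueError(f"unknown planted-variant kind {kind!r}")


def export_dataset(bundle: DatasetBundle, outdir) -> dict[str, Path]:
    """Write the bundle as FASTA/GFF3/VCF/TSV files (standard-conformant,
    1-based at the boundary); round-trips through io_formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "panel.vcf",
        "qtl": outdir / "qtls.tsv",
        "popmap": outdir / "popmap.tsv",
        "truth_sweeps": outdir / "truth_sweeps.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
    }
    iof.write_fasta(bundle.reference, paths["fasta"])
    iof.write_gff3(bundle.annotation, paths["gff3"])
    iof.write_vcf(bundle.panel, paths["vcf"], bundle.chrom_lengths)
    iof.write_qtl_table(bundle.qtls, paths["qtl"])
    iof.write_popmap(bundle.popmap, paths["popmap"])
    pd.DataFrame([{"chrom": s.chrom, "pos": s.pos, "lam": s.lam,
                   "t_fix": s.t_fix if s.t_fix is not None
                   else bundle.truth.model.T1}
                  for s in bundle.truth.sweeps]).to_csv(
        paths["truth_sweeps"], sep="\t", index=False)
    bundle.truth.planted_variants.to_csv(paths["truth_variants"], sep="\t",
                                         index=False)
    return paths
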