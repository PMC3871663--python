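"""File formats and SNP-level filtering.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based conventions of VCF and GFF3 happens only in the readers and writers
here.  Genotypes are haploid-coded (the accessions this pipeline targets are
inbred): homozygous diploid calls collapse to a single allele and
heterozygous or half calls become missing.
"""

from __future__ import annotations

import logging
import textwrap
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

SITE_CLASSES = ("synonymous", "nonsynonymous", "UTR", "intron",
                "intergenic", "unknown")

#: canonical population labels and the derived groupings built from them
DERIVED_GROUPS = {
    "japonica": frozenset({"japonica_temperate", "japonica_tropical"}),
    "sativa": frozenset({"indica", "japonica_temperate", "japonica_tropical"}),
    "cultivated": frozenset({"indica", "japonica_temperate",
                             "japonica_tropical", "cult"}),
    "wild": frozenset({"rufipogon", "wild"}),
}


class PopulationMap:
    """Sample -> population assignment with derived group resolution."""

    def __init__(self, assignments: dict[str, str],
                 derived: dict[str, frozenset] | None = None):
        self.assignments = dict(assignments)
        self.derived = dict(DERIVED_GROUPS if derived is None else derived)

    def labels_in(self, group: str) -> frozenset:
        return self.derived.get(group, frozenset({group}))

    def samples_in(self, group: str) -> list[str]:
        labels = self.labels_in(group)
        return [s for s, p in self.assignments.items() if p in labels]

    def indices_in(self, samples: list[str], group: str) -> np.ndarray:
        labels = self.labels_in(group)
        return np.array([i for i, s in enumerate(samples)
                         if self.assignments.get(s) in labels], dtype=int)

    def __len__(self):
        return len(self.assignments)

    def __eq__(self, other):
        return (isinstance(other, PopulationMap)
                and self.assignments == other.assignments)


@dataclass
class GenotypePanel:
    """Accessions x biallelic sites with per-site metadata.

    ``alleles`` is (n_samples, n_sites) int8 over {0: ref/ancestral,
    1: alt/derived, -1: missing}.  ``sites`` columns: chrom, pos (0-based),
    ref, alt, qual, depth, site_class.
    """

    samples: list[str]
    alleles: np.ndarray
    sites: pd.DataFrame

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.samples), len(self.sites)):
            raise ValueError("alleles shape does not match samples x sites")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def take_sites(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(self.samples, self.alleles[:, idx],
                             self.sites.iloc[idx].reset_index(drop=True))

    def for_chrom(self, chrom: str) -> "GenotypePanel":
        return self.take_sites((self.sites["chrom"] == chrom).to_numpy())


@dataclass
class Gene:
    """One gene model: genomic coordinates 0-based half-open, CDS in
    transcript order is obtained strand-aware from ``cds`` intervals."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: list[tuple[int, int]]
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Transcription start: start of first exon on +, last base on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def usable(self) -> bool:
        return self.cds_length % 3 == 0 and self.cds_length > 0

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        cached = getattr(self, "_cds_pos", None)
        if cached is not None:
            return cached
        parts = [np.arange(s, e) for s, e in sorted(self.cds)]
        pos = np.concatenate(parts) if parts else np.array([], dtype=int)
        if self.strand != "+":
            pos = pos[::-1]
        object.__setattr__(self, "_cds_pos", pos)
        return pos


class GeneAnnotation:
    """Collection of gene models with interval lookup."""

    def __init__(self, genes: list[Gene]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for gl in self._by_chrom.values():
            gl.sort(key=lambda g: g.start)
        #: gene_id -> genomic positions of synonymous-class sites in
        #: transcript order (attach via annotate.attach_synonymous_sites)
        self.syn_sites: dict[str, np.ndarray] = {}

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def genes_in(self, chrom: str, start: int, end: int) -> list[Gene]:
        return [g for g in self.genes_on(chrom)
                if g.start < end and g.end > start]

    def __len__(self):
        return len(self.genes)


@dataclass
class FilterReport:
    n_input: int = 0
    removed_low_qual: int = 0
    removed_low_depth: int = 0
    removed_high_depth: int = 0

    @property
    def n_passed(self) -> int:
        return (self.n_input - self.removed_low_qual
                - self.removed_low_depth - self.removed_high_depth)


# ---------------------------------------------------------------------------
# readers


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "population"} <= set(df.columns):
        raise ValueError("popmap needs columns: sample, population")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def read_vcf_panel(vcf_path, popmap_path) -> tuple[GenotypePanel, PopulationMap]:
    """Load a VCF into a haploid-coded panel.

    Homozygous diploid genotypes collapse to one allele; heterozygous or
    half-called genotypes become missing; multi-allelic sites are dropped
    (count logged).
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in popmap.assignments]
    if unmapped:
        raise ValueError(f"samples absent from popmap: {unmapped}")
    cols = []
    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.genotypes, dtype=int)
        a = np.full(len(samples), MISSING, dtype=np.int8)
        hom = (gt[:, 0] == gt[:, 1]) & (gt[:, 0] >= 0)
        a[hom] = gt[hom, 0]
        cols.append(a)
        dp = v.INFO.get("DP")
        if dp is None:
            d = v.format("DP")
            dp = float(np.nanmean(d)) if d is not None else np.nan
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0],
                     np.nan if v.QUAL is None else float(v.QUAL),
                     float(dp) if dp is not None else np.nan, "unknown"))
    if n_multi:
        log.info("dropped %d non-biallelic sites", n_multi)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "qual", "depth", "site_class"])
    alleles = (np.stack(cols, axis=1) if cols
               else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypePanel(samples, alleles, sites), popmap


def apply_snp_filters(panel: GenotypePanel, min_qual: float = 100.0,
                      min_depth: float = 3.0,
                      max_depth_exclusive: float = 100.0
                      ) -> tuple[GenotypePanel, FilterReport]:
    """Keep sites with qual >= min_qual and min_depth <= depth < max_depth.

    Sites are counted under the first threshold they fail (quality, then
    low depth, then high depth).  If an annotation column is entirely
    missing the corresponding criterion passes with a warning.
    """
    rep = FilterReport(n_input=panel.n_sites)
    qual = panel.sites["qual"].to_numpy(dtype=float)
    depth = panel.sites["depth"].to_numpy(dtype=float)
    if np.all(np.isnan(qual)):
        log.warning("no quality annotations; quality filter skipped")
        qual = np.full_like(qual, np.inf)
    if np.all(np.isnan(depth)):
        log.warning("no depth annotations; depth filter skipped")
        depth = np.full_like(depth, min_depth)
    bad_q = qual < min_qual
    bad_dlo = ~bad_q & (depth < min_depth)
    bad_dhi = ~bad_q & ~bad_dlo & (depth >= max_depth_exclusive)
    rep.removed_low_qual = int(bad_q.sum())
    rep.removed_low_depth = int(bad_dlo.sum())
    rep.removed_high_depth = int(bad_dhi.sum())
    keep = ~(bad_q | bad_dlo | bad_dhi)
    return panel.take_sites(keep), rep


def read_gene_annotation(gff3_path) -> GeneAnnotation:
    """Parse gene/mRNA/exon/CDS features from GFF3 into gene models."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end)
               for c in db.children(g, featuretype="CDS", order_by="start")]
        exons = [(e.start - 1, e.end)
                 for e in db.children(g, featuretype="exon", order_by="start")]
        gene = Gene(gene_id=g.id, chrom=g.seqid, strand=g.strand,
                    start=g.start - 1, end=g.end, cds=cds, exons=exons)
        if not gene.usable:
            log.warning("gene %s CDS length %d not divisible by 3; "
                        "flagged unusable for codon effects",
                        gene.gene_id, gene.cds_length)
        genes.append(gene)
    return GeneAnnotation(genes)


def read_qtl_table(path) -> pd.DataFrame:
    """Read a GRAMENE-style QTL TSV (id, trait, category, chrom, start, end).

    Coordinates convert to 0-based half-open.  Rows with start > end are
    swapped with a warning; rows with non-numeric coordinates are rejected
    with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "trait", "category", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"QTL table missing columns: {missing}")
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    bad = start.isna() | end.isna()
    for i in df.index[bad]:
        log.warning("QTL table line %d rejected: non-numeric coordinates",
                    i + 2)
    df = df[~bad].copy()
    start, end = start[~bad].astype(int), end[~bad].astype(int)
    swapped = start > end
    if swapped.any():
        log.warning("QTL table: swapped start/end on %d rows",
                    int(swapped.sum()))
        start, end = start.where(~swapped, end), end.where(~swapped, start)
    df["start"] = start - 1
    df["end"] = end
    return df.reset_index(drop=True)


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# writers


def write_fasta(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 70)) + "\n")


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


def write_qtl_table(qtls: pd.DataFrame, path) -> None:
    out = qtls.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tsweepqtl\tgene\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{g.chrom}\tsweepqtl\tmRNA\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(f"{g.chrom}\tsweepqtl\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n")
            cds_tx = sorted(g.cds, reverse=(g.strand == "-"))
            done = 0
            for i, (s, e) in enumerate(cds_tx, 1):
                phase = (3 - done % 3) % 3
                fh.write(f"{g.chrom}\tsweepqtl\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t{phase}\tID={mrna}.cds{i};Parent={mrna}\n")
                done += e - s


def write_vcf(panel: GenotypePanel, path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write the panel as VCF v4.2 (diploid homozygous GT encoding)."""
    gt_code = {0: "0/0", 1: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=sweepqtl\n")
        if contig_lengths:
            for name, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,'
                 'Description="Site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        sites = panel.sites
        for j in range(panel.n_sites):
            row = sites.iloc[j]
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:.2f}"
            info = ("." if pd.isna(row["depth"])
                    else f"DP={int(row['depth'])}")
            gts = "\t".join(gt_code[int(a)] for a in panel.alleles[:, j])
            fh.write(f"{row['chrom']}\t{row['pos'] + 1}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t{qual}\t.\t{info}\tGT\t{gts}\n")
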