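"""Variant effects, QTL co-localization, and the fixed-variant screen.

Effect classes follow the screening rules for domestication candidates:
coding SNPs translate ref vs alt codons (replacement vs silent), coding
indels are frameshift unless their length is a multiple of three, and
variants within 200 bp upstream or 100 bp downstream of an annotated
transcription start site (strand-aware) are regulatory candidates.
A variant is reported by the screen only when it is fixed among called
cultivated accessions, its per-site Hudson F_ST against the wild group
reaches the threshold, and per-group coverage minima are met.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import stats
from .io_formats import Gene, GeneAnnotation, GenotypePanel, PopulationMap

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: standard-code translation table, indexed by codon string
_CODON_AA = {a + b + c: str(Seq(a + b + c).translate())
             for a in "ACGT" for b in "ACGT" for c in "ACGT"}
#: 2-base prefixes whose third position is fourfold degenerate
_FOURFOLD = {p for p in {c[:2] for c in _CODON_AA}
             if len({_CODON_AA[p + b] for b in "ACGT"}) == 1}

UPSTREAM_BP = 200
DOWNSTREAM_BP = 100

REPORTABLE_CLASSES = ("replacement", "frameshift", "upstream", "downstream")

#: keyword lists used to match GRAMENE-style trait categories
HIGHLIGHT_KEYWORDS = {
    "shattering": ("shatter",),
    "awn": ("awn",),
    "dormancy": ("dormancy", "germination"),
    "quality": ("quality",),
}


def _tx_base(base: str, strand: str) -> str:
    return base if strand == "+" else base.translate(_COMPLEMENT)


def _codon_at(gene: Gene, reference: dict[str, str], cds_index: int) -> str:
    pos = gene.cds_positions()
    codon_pos = pos[3 * (cds_index // 3): 3 * (cds_index // 3) + 3]
    seq = reference[gene.chrom]
    return "".join(_tx_base(seq[p], gene.strand) for p in codon_pos)


def _translate(codon: str) -> str:
    return _CODON_AA[codon.upper()]


def _cds_index(gene: Gene, pos: int) -> int | None:
    """Transcript-order CDS offset of a genomic position, or None."""
    intervals = sorted(gene.cds)
    off = 0
    if gene.strand == "+":
        for s, e in intervals:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
    else:
        for s, e in reversed(intervals):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
    return None


def attach_synonymous_sites(annotation: GeneAnnotation,
                            reference: dict[str, str]) -> GeneAnnotation:
    """Record, per usable gene, the genomic positions of synonymous-class
    sites (fourfold-degenerate third codon positions) in transcript order
    from the translation start."""
    for gene in annotation.genes:
        if not gene.usable:
            continue
        pos = gene.cds_positions()
        seq = reference[gene.chrom]
        cds = "".join(_tx_base(seq[p], gene.strand) for p in pos)
        syn = [pos[3 * c + 2] for c in range(len(cds) // 3)
               if cds[3 * c: 3 * c + 2].upper() in _FOURFOLD]
        annotation.syn_sites[gene.gene_id] = np.array(syn, dtype=np.int64)
    return annotation


def classify_variant_effect(variant, annotation: GeneAnnotation,
                            reference: dict[str, str]) -> str:
    """Effect class for one variant (chrom, pos, ref, alt), pos 0-based.

    Returns one of replacement | silent | frameshift | in_frame_indel |
    upstream | downstream | other.
    """
    chrom, pos, ref, alt = (variant["chrom"], int(variant["pos"]),
                            str(variant["ref"]), str(variant["alt"])) \
        if isinstance(variant, (dict, pd.Series)) else variant
    pos = int(pos)
    if chrom not in reference:
        raise ValueError(f"variant on unannotated chromosome {chrom!r}")
    is_indel = len(ref) != len(alt)
    win = UPSTREAM_BP + len(ref) + 1
    candidates = annotation.genes_in(chrom, pos - win, pos + win)
    if is_indel:
        shift = abs(len(ref) - len(alt))
        span = (pos + 1, pos + 1 + max(len(ref) - 1, 1))
        for gene in candidates:
            if not gene.usable:
                continue
            for s, e in gene.cds:
                if span[0] < e and span[1] > s:
                    return "frameshift" if shift % 3 else "in_frame_indel"
    else:
        for gene in candidates:
            if not gene.usable:
                continue
            ci = _cds_index(gene, pos)
            if ci is not None:
                codon = _codon_at(gene, reference, ci)
                off = ci % 3
                alt_codon = (codon[:off] + _tx_base(alt, gene.strand)
                             + codon[off + 1:])
                return ("silent" if _translate(codon) == _translate(alt_codon)
                        else "replacement")
    for gene in candidates:
        t = gene.tss
        if gene.strand == "+":
            if t - UPSTREAM_BP <= pos < t:
                return "upstream"
            if t <= pos < t + DOWNSTREAM_BP:
                return "downstream"
        else:
            if t < pos <= t + UPSTREAM_BP:
                return "upstream"
            if t - DOWNSTREAM_BP < pos <= t:
                return "downstream"
    return "other"


def classify_sites(panel: GenotypePanel, annotation: GeneAnnotation,
                   reference: dict[str, str]) -> list[str]:
    """Site class per panel site: synonymous | nonsynonymous | UTR |
    intron | intergenic | unknown (indels and broken gene models)."""
    classes = np.full(panel.n_sites, "intergenic", dtype=object)
    sites = panel.sites
    all_pos = sites["pos"].to_numpy()
    all_ref = sites["ref"].to_numpy()
    all_alt = sites["alt"].to_numpy()
    for chrom in panel.chroms():
        genes = annotation.genes_on(chrom)
        starts = np.array([g.start for g in genes], dtype=np.int64)
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        gi = np.searchsorted(starts, all_pos[idx], side="right") - 1
        for k, j in enumerate(idx):
            pos = int(all_pos[j])
            ref, alt = str(all_ref[j]), str(all_alt[j])
            if len(ref) != len(alt):
                classes[j] = "unknown"
                continue
            gene = None
            for back in (0, 1):  # tolerate overlapping gene models
                gidx = gi[k] - back
                if gidx >= 0 and genes[gidx].start <= pos < genes[gidx].end:
                    gene = genes[gidx]
                    break
            if gene is None:
                continue
            if any(s <= pos < e for s, e in gene.cds):
                if not gene.usable:
                    classes[j] = "unknown"
                    continue
                ci = _cds_index(gene, pos)
                codon = _codon_at(gene, reference, ci)
                off = ci % 3
                alt_codon = (codon[:off] + _tx_base(alt, gene.strand)
                             + codon[off + 1:])
                classes[j] = ("synonymous"
                              if _translate(codon) == _translate(alt_codon)
                              else "nonsynonymous")
            elif any(s <= pos < e for s, e in gene.exons):
                classes[j] = "UTR"
            else:
                classes[j] = "intron"
    return list(classes)


def _as_region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame([{
        "label": r.label, "chrom": r.chrom, "start": r.start, "end": r.end,
    } for r in regions])


def map_qtls_to_regions(qtls: pd.DataFrame, regions,
                        span_limit: int = 5_000_000, pad: int = 2_000_000,
                        highlight: dict[str, tuple] | None = None,
                        chroms: list[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map QTL midpoints to candidate regions.

    QTLs spanning more than ``span_limit`` are dropped; a QTL maps to a
    region iff its midpoint lies within [start - pad, end + pad].  Returns
    (per-region QTL table, per-region counts by highlighted category).
    """
    regions = _as_region_frame(regions)
    if chroms is not None:
        bad = sorted(set(qtls["chrom"]) - set(chroms))
        if bad:
            raise ValueError(f"QTL chromosomes not in panel: {bad}")
    highlight = HIGHLIGHT_KEYWORDS if highlight is None else highlight
    q = qtls.copy()
    q["span"] = q["end"] - q["start"]
    q = q[q["span"] <= span_limit].copy()
    q["midpoint"] = (q["start"] + q["end"]) // 2

    def _category(row):
        text = f"{row['trait']} {row['category']}".lower()
        for name, keys in highlight.items():
            if any(k in text for k in keys):
                return name
        return ""

    q["highlight"] = q.apply(_category, axis=1) if len(q) else ""
    hits = []
    for _, reg in regions.iterrows():
        sel = q[(q["chrom"] == reg["chrom"])
                & (q["midpoint"] >= reg["start"] - pad)
                & (q["midpoint"] <= reg["end"] + pad)]
        for _, row in sel.iterrows():
            hits.append({"region": reg["label"], "qtl_id": row["id"],
                         "trait": row["trait"], "category": row["category"],
                         "chrom": row["chrom"], "midpoint": row["midpoint"],
                         "span": row["span"], "highlight": row["highlight"]})
    mapped = pd.DataFrame(hits, columns=["region", "qtl_id", "trait",
                                         "category", "chrom", "midpoint",
                                         "span", "highlight"])
    counts = []
    for _, reg in regions.iterrows():
        sel = mapped[mapped["region"] == reg["label"]]
        row = {"region": reg["label"], "n_qtls": len(sel)}
        for name in highlight:
            row[f"n_{name}"] = int((sel["highlight"] == name).sum())
        counts.append(row)
    return mapped, pd.DataFrame(counts)


def screen_fixed_variants(panel: GenotypePanel, popmap: PopulationMap,
                          regions, annotation: GeneAnnotation,
                          reference: dict[str, str],
                          fst_threshold: float = 0.7,
                          min_wild: int = 6, min_cult: int = 12,
                          cult_group: str = "sativa",
                          wild_group: str = "rufipogon") -> pd.DataFrame:
    """Fixed-variant screen over candidate regions.

    Reports variants of class replacement/frameshift/upstream/downstream
    that are monomorphic among called cultivated accessions, reach the
    per-site F_ST threshold against the wild group, and meet the per-group
    called-sample minima.
    """
    regions = _as_region_frame(regions)
    wi = popmap.indices_in(panel.samples, wild_group)
    ci = popmap.indices_in(panel.samples, cult_group)
    seen: set[tuple] = set()
    out = []
    for _, reg in regions.iterrows():
        sites = panel.sites
        in_reg = ((sites["chrom"] == reg["chrom"])
                  & (sites["pos"] >= reg["start"])
                  & (sites["pos"] < reg["end"]))
        for j in np.flatnonzero(in_reg.to_numpy()):
            row = sites.iloc[j]
            key = (row["chrom"], int(row["pos"]))
            if key in seen:
                continue
            a_w = panel.alleles[wi, j]
            a_c = panel.alleles[ci, j]
            n_w = int((a_w >= 0).sum())
            n_c = int((a_c >= 0).sum())
            if n_w < min_wild or n_c < min_cult:
                continue
            cult_alleles = a_c[a_c >= 0]
            if not np.all(cult_alleles == cult_alleles[0]):
                continue
            within, between, valid = stats.fst_site_components(
                a_w[:, None], a_c[:, None])
            if not valid[0] or between[0] <= 0:
                continue
            fst = 1.0 - within[0] / between[0]
            if fst < fst_threshold:
                continue
            effect = classify_variant_effect(
                (row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                annotation, reference)
            if effect not in REPORTABLE_CLASSES:
                continue
            genes = annotation.genes_in(row["chrom"], int(row["pos"]),
                                        int(row["pos"]) + 1)
            seen.add(key)
            out.append({
                "chrom": row["chrom"], "pos": int(row["pos"]),
                "ref": row["ref"], "alt": row["alt"],
                "gene_id": genes[0].gene_id if genes else "",
                "effect": effect,
                "cult_allele": int(cult_alleles[0]),
                "n_called_wild": n_w, "n_called_cult": n_c,
                "fst": float(fst), "region": reg["label"],
            })
    cols = ["chrom", "pos", "ref", "alt", "gene_id", "effect", "cult_allele",
            "n_called_wild", "n_called_cult", "fst", "region"]
    df = pd.DataFrame(out, columns=cols)
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def write_reports(outdir, regions, qtl_map: pd.DataFrame,
                  variants: pd.DataFrame,
                  annotation: GeneAnnotation | None = None,
                  tracks: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the report bundle: region summary, QTLs per region, genes per
    region, and the fixed-variant table, in deterministic genomic order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = _as_region_frame(regions)
    paths = {}
    reg = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    paths["regions"] = outdir / "regions.tsv"
    reg.to_csv(paths["regions"], sep="\t", index=False)
    paths["qtls"] = outdir / "qtls_by_region.tsv"
    qtl_map.sort_values(["region", "chrom", "midpoint"]).to_csv(
        paths["qtls"], sep="\t", index=False)
    gene_rows = []
    if annotation is not None:
        for _, r in reg.iterrows():
            for g in annotation.genes_in(r["chrom"], int(r["start"]),
                                         int(r["end"])):
                gene_rows.append({"region": r["label"], "gene_id": g.gene_id,
                                  "chrom": g.chrom, "start": g.start,
                                  "end": g.end, "strand": g.strand})
    paths["genes"] = outdir / "genes_by_region.tsv"
    pd.DataFrame(gene_rows, columns=["region", "gene_id", "chrom", "start",
                                     "end", "strand"]).to_csv(
        paths["genes"], sep="\t", index=False)
    paths["variants"] = outdir / "fixed_variants.tsv"
    variants.to_csv(paths["variants"], sep="\t", index=False)
    if tracks is not None:
        paths["tracks"] = outdir / "window_tracks.tsv"
        tracks.to_csv(paths["tracks"], sep="\t", index=False)
    return paths
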