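"""End-to-end orchestration: simulate -> filter -> stats -> demography ->
null -> scan -> F_ST scan -> QTL map -> screen -> report.

A single run seed expands into per-stage seeds through a counter scheme
(SeedSequence([seed, stage_index])); every stochastic stage logs its
derived seed in the run manifest.  The synthetic dataset is always written
to disk and read back through the standard readers before analysis, so a
cached dataset and a fresh one follow the identical code path, and deleting
any intermediate reproduces identical downstream outputs on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, demography, diffscan, io_formats, simdata, stats
from . import sweepscan

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_STAGES = ("simulate", "filter", "stats", "demography", "null", "scan",
           "fst", "qtl", "screen", "report")


def stage_seed(run_seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([run_seed, idx]).generate_state(1)[0]
               % 2**31)


@dataclass
class PipelineConfig:
    genome: dict
    model: dict
    scan: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    demography: dict = field(default_factory=lambda: {"mode": "truth"})
    fst: dict = field(default_factory=dict)
    qtl: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scan = {"window": 500_000, "step": 20_000, "K": 15,
                     "R_null": 10_000, "wild": "rufipogon",
                     "cult": "sativa", "site_mask": "all", **self.scan}
        self.filters = {"min_qual": 100.0, "min_depth": 3.0,
                        "max_depth": 100.0, **self.filters}
        self.fst = {"pairs": [["indica", "japonica"],
                              ["japonica_temperate", "japonica_tropical"]],
                    "K": 1, **self.fst}
        self.qtl = {"span_limit": 5_000_000, "pad": 2_000_000, **self.qtl}
        self.screen = {"fst_threshold": 0.7, "min_wild": 6, "min_cult": 12,
                       "cult_group": "sativa", **self.screen}
        s = self.scan
        if s["step"] <= 0 or s["window"] <= 0 or s["step"] > s["window"]:
            raise ConfigError("scan: need 0 < step <= window")
        if s["R_null"] < 1:
            raise ConfigError("scan: R_null must be >= 1")
        if "chrom_lengths" not in self.genome:
            raise ConfigError("genome: chrom_lengths is required")
        short = [c for c, ln in self.genome["chrom_lengths"].items()
                 if ln < s["window"]]
        if short:
            raise ConfigError(f"chromosomes shorter than the scan window: "
                              f"{short}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {"genome", "model", "scan", "filters", "demography", "fst",
                 "qtl", "screen"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def build_model(self) -> simdata.DemographicModel:
        return simdata.default_model(**self.model)

    def build_genome_config(self) -> simdata.GenomeConfig:
        g = dict(self.genome)
        g.pop("plant_variants", None)
        sweeps = tuple(simdata.SweepSpec(**sw) for sw in g.pop("sweeps", []))
        return simdata.GenomeConfig(sweeps=sweeps, **g)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_dataset(cfg: PipelineConfig, data_dir: Path):
    panel, popmap = io_formats.read_vcf_panel(data_dir / "panel.vcf",
                                              data_dir / "popmap.tsv")
    annotation = io_formats.read_gene_annotation(data_dir / "genes.gff3")
    reference = io_formats.read_fasta(data_dir / "reference.fasta")
    annotate.attach_synonymous_sites(annotation, reference)
    panel.sites["site_class"] = annotate.classify_sites(panel, annotation,
                                                        reference)
    qtls = io_formats.read_qtl_table(data_dir / "qtls.tsv")
    truth_sweeps = pd.read_csv(data_dir / "truth_sweeps.tsv", sep="\t") \
        if (data_dir / "truth_sweeps.tsv").stat().st_size > 1 else None
    return panel, popmap, annotation, reference, qtls, truth_sweeps


def run_pipeline(config, seed: int, outdir) -> dict:
    """Execute all stages; returns results plus a run manifest."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": int(seed),
                "stage_seeds": {s: stage_seed(seed, s) for s in _STAGES
                                if s in ("simulate", "null", "demography")},
                "parameters": {"scan": config.scan, "model": config.model,
                               "filters": config.filters,
                               "qtl": config.qtl, "screen": config.screen},
                "counts": {}}

    # --- simulate (cached on disk) ---------------------------------------
    data_dir = outdir / "data"
    if not (data_dir / "panel.vcf").exists():
        log.info("stage simulate: seed %d", stage_seed(seed, "simulate"))
        model = config.build_model()
        gcfg = config.build_genome_config()
        bundle = simdata.synthesize_genome(gcfg, model,
                                           seed=stage_seed(seed, "simulate"))
        pv = config.genome.get("plant_variants")
        if pv:
            bundle = simdata.plant_screen_variants(
                bundle, pv["chrom"], tuple(pv["region"]),
                seed=stage_seed(seed, "simulate"))
        simdata.export_dataset(bundle, data_dir)
    panel, popmap, annotation, reference, qtls, truth_sweeps = \
        _load_dataset(config, data_dir)
    manifest["counts"]["n_sites_raw"] = panel.n_sites

    # --- SNP filters ------------------------------------------------------
    f = config.filters
    panel, filter_report = io_formats.apply_snp_filters(
        panel, f["min_qual"], f["min_depth"], f["max_depth"])
    manifest["counts"]["n_sites_filtered"] = panel.n_sites
    manifest["counts"]["filter_report"] = vars(filter_report).copy()

    # --- window tracks ----------------------------------------------------
    s = config.scan
    tracks = []
    for chrom in panel.chroms():
        grid = stats.sliding_windows(
            _chrom_length(config, chrom), s["window"], s["step"], chrom)
        mask = None
        if s["site_mask"] == "genes":
            sub = panel.for_chrom(chrom).sites
            mask = (sub["site_class"] != "intergenic").to_numpy()
        tracks.append(sweepscan.ratio_track(panel, popmap, grid, s["cult"],
                                            s["wild"], site_mask=mask))
    track = pd.concat(tracks, ignore_index=True)

    # --- demographic model for the null ----------------------------------
    model = config.build_model()
    if config.demography.get("mode", "truth") == "infer":
        model = _infer_model(config, panel, annotation, popmap, model,
                             stage_seed(seed, "demography"), manifest)

    # --- simulation null (cached) -----------------------------------------
    null_path = outdir / "null_distribution.tsv"
    if null_path.exists():
        df = pd.read_csv(null_path, sep="\t")
        null = sweepscan.NullDistribution(
            model, _n_group(popmap, s["wild"]), _n_group(popmap, s["cult"]),
            s["window"], len(df), df["ratio_pi"].to_numpy(),
            df["ratio_theta"].to_numpy(), stage_seed(seed, "null"))
    else:
        null = sweepscan.build_null_distribution(
            model, _n_group(popmap, s["wild"]), _n_group(popmap, s["cult"]),
            s["window"], s["R_null"], seed=stage_seed(seed, "null"),
            locus_size=config.genome.get("locus_size", 5_000))
        pd.DataFrame({"ratio_pi": null.ratios_pi,
                      "ratio_theta": null.ratios_theta}).to_csv(
            null_path, sep="\t", index=False)

    # --- scoring and region calling ---------------------------------------
    scored = sweepscan.score_windows(track, null, s["window"])
    regions = sweepscan.call_sweep_regions(scored, K=s["K"])
    region_frame = sweepscan.regions_to_frame(regions)
    manifest["counts"]["n_sweep_regions"] = len(regions)

    # --- F_ST differentiation scans ----------------------------------------
    fst_tracks, fst_regions = [], []
    for pair in config.fst["pairs"]:
        a, b = pair
        if (_n_group(popmap, a) < 2 or _n_group(popmap, b) < 2):
            continue
        for chrom in panel.chroms():
            grid = stats.sliding_windows(
                _chrom_length(config, chrom), s["window"], s["step"], chrom)
            ft = diffscan.fst_scan(panel, popmap, a, b, grid)
            ft["pair"] = f"{a}-{b}"
            fst_tracks.append(ft)
        pair_track = pd.concat([t for t in fst_tracks
                                if t["pair"].iloc[0] == f"{a}-{b}"],
                               ignore_index=True)
        fst_regions.extend(diffscan.top_fst_regions(
            pair_track, K=config.fst["K"], prefix=f"{a[:1].upper()}F"))
    fst_track = (pd.concat(fst_tracks, ignore_index=True)
                 if fst_tracks else pd.DataFrame())
    manifest["counts"]["n_fst_regions"] = len(fst_regions)

    # --- QTL co-localization ----------------------------------------------
    all_regions = region_frame
    if fst_regions:
        fr = pd.DataFrame([vars(r) for r in fst_regions])
        all_regions = pd.concat(
            [region_frame, fr[["label", "chrom", "start", "end"]]],
            ignore_index=True)
    qtl_map, qtl_counts = annotate.map_qtls_to_regions(
        qtls, all_regions, config.qtl["span_limit"], config.qtl["pad"],
        chroms=list(config.genome["chrom_lengths"]))
    manifest["counts"]["n_qtls_mapped"] = len(qtl_map)

    # --- fixed-variant screen ----------------------------------------------
    sc = config.screen
    variants = annotate.screen_fixed_variants(
        panel, popmap, all_regions, annotation, reference,
        sc["fst_threshold"], sc["min_wild"], sc["min_cult"],
        sc["cult_group"])
    manifest["counts"]["n_fixed_variants"] = len(variants)

    # --- reports ------------------------------------------------------------
    report_dir = outdir / "reports"
    paths = annotate.write_reports(report_dir, all_regions, qtl_map,
                                   variants, annotation=annotation,
                                   tracks=scored)
    qtl_counts.to_csv(report_dir / "qtl_counts_by_region.tsv", sep="\t",
                      index=False)
    if len(fst_track):
        fst_track.to_csv(report_dir / "fst_tracks.tsv", sep="\t",
                         index=False)
    manifest["files"] = {p.name: _sha256(p)
                         for p in sorted(report_dir.glob("*.tsv"))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"panel": panel, "popmap": popmap, "annotation": annotation,
            "track": scored, "regions": regions, "fst_regions": fst_regions,
            "fst_track": fst_track, "qtl_map": qtl_map,
            "variants": variants, "truth_sweeps": truth_sweeps,
            "manifest": manifest, "outdir": outdir, "null": null}


def _chrom_length(config: PipelineConfig, chrom: str) -> int:
    return int(config.genome["chrom_lengths"][chrom])


def _n_group(popmap, group: str) -> int:
    return len(popmap.samples_in(group))


def _infer_model(config, panel, annotation, popmap, model, dseed, manifest):
    d = config.demography
    loci = demography.summarize_loci(panel, annotation, popmap,
                                     wild_group=config.scan["wild"],
                                     cult_group=config.scan["cult"])
    if len(loci) < 10:
        log.warning("too few inference loci (%d); keeping configured model",
                    len(loci))
        return model
    n_w = _n_group(popmap, config.scan["wild"])
    n_c = _n_group(popmap, config.scan["cult"])
    R = int(d.get("R", 1000))
    n0_grid = model.Ne_wild * np.geomspace(0.25, 4.0, 5)
    _, n0_mle = demography.estimate_n0(loci, n_w, model.mu, n0_grid,
                                       R=R, seed=dseed)
    n1_grid, t1_grid = demography.default_grids(n0_mle,
                                                int(d.get("grid_points", 5)))
    surface = demography.bottleneck_likelihood_surface(
        loci, n_w, n_c, n0_mle, model.mu, n1_grid, t1_grid, R=R, seed=dseed)
    (n1_mle, t1_mle), _ = demography.bottleneck_mle(surface)
    manifest["counts"]["demography_mle"] = {
        "N0_eff": n0_mle, "N1_eff": n1_mle, "T1": t1_mle,
        "n_loci": len(loci)}
    # inferred sizes are effective; convert back to census under the
    # configured selfing rates
    return simdata.DemographicModel(
        N0=n0_mle * (1 + model.F_wild), N1=n1_mle * (1 + model.F_cult),
        T1=t1_mle, mu=model.mu, rec=model.rec,
        s_wild=model.s_wild, s_cult=model.s_cult)
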