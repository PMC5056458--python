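"""End-to-end orchestration: simulate/load -> filter -> scan -> call ->
compare -> origin, with a single config, seeded determinism and tabular
outputs.

The stage chain mirrors the scan analysis it packages: pooled-heterozygosity,
Tajima's D and FST window scans with genome-wide Z-scores; flagged windows
merged into sweep regions (lower-tail -4 for Hp and Tajima's D, upper-tail
+4 for FST); cross-method overlap; and per-region origin assignment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .origin import region_origin
from .painting import PainterParams
from .simulate import SimParams, simulate, sweeps_to_regions, write_fixture
from .sweep_calls import (flag_windows, genes_near, merge_windows,
                          overlap_regions, region_summary)
from .variant_io import (GenomeLayout, filter_sites, read_bed, read_variants,
                         write_bed)
from .window_stats import scan_fst, scan_hp, scan_tajima

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config for the whole chain.

    Either ``simulate`` holds SimParams (fixture mode) or ``vcf``/``layout``
    point at input files with ``individuals``/``pools`` declaring sample
    roles.  Thresholds and window geometry default to the standard scan
    settings (40 kb windows, 20 kb step, -4 lower / +4 upper tails).
    """

    outdir: str = "feralscan_out"
    seed: int = 0
    simulate: SimParams | None = None
    vcf: str | None = None
    layout: str | None = None
    individuals: list[str] | None = None
    pools: list[str] = field(default_factory=lambda: ["wild_pool",
                                                      "domestic_pool"])
    wild_pool: str = "wild_pool"
    domestic_pool: str = "domestic_pool"
    window_size: int = 40_000
    window_step: int = 20_000
    hp_threshold: float = -4.0
    hp_extreme_threshold: float = -6.0
    tajima_threshold: float = -4.0
    fst_threshold: float = 4.0
    min_alt_support: int = 2
    min_complete: float = 0.8
    gene_margin: int = 40_000
    annotation_bed: str | None = None
    painter: PainterParams = field(default_factory=PainterParams)
    n_donor_haplotypes: int = 16

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = SimParams(**self.simulate)
        if isinstance(self.painter, dict):
            self.painter = PainterParams(**self.painter)
        for name in ("hp_threshold", "tajima_threshold", "fst_threshold"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.simulate is None:
            if self.vcf is None or self.layout is None:
                raise ValueError("need either simulate params or vcf+layout")
            for p in (self.vcf, self.layout):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.simulate is not None and self.simulate.seed != self.seed:
            self.simulate = dataclasses.replace(self.simulate, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output (also written to outdir)."""

    config: PipelineConfig
    scans: dict[str, pd.DataFrame]
    regions: dict[str, pd.DataFrame]
    comparisons: dict[str, dict]
    origins: pd.DataFrame
    genes: pd.DataFrame | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write TSV/BED/JSON artefacts under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        logger.info("stage simulate: %s", config.simulate)
        _, feral, table = simulate(config.simulate)
        layout = config.simulate.layout()
        write_fixture(config.simulate, table, outdir / "sim")
        truth = sweeps_to_regions(config.simulate.sweeps)
    else:
        layout = GenomeLayout.from_tsv(config.layout)
        table = read_variants(config.vcf, layout,
                              individuals=config.individuals,
                              pools=config.pools)
        truth = None

    # --- filter -----------------------------------------------------------
    table = filter_sites(table, config.min_alt_support, config.min_complete)
    logger.info("stage filter: %d sites retained", table.n_sites)

    # --- scans ------------------------------------------------------------
    size, step = config.window_size, config.window_step
    scans: dict[str, pd.DataFrame] = {}
    scans["hp"] = scan_hp(table, layout, "genotypes", size, step)
    scans["tajima"] = scan_tajima(table, layout, size, step)
    for pool in table.pools:
        scans[f"hp_{pool}"] = scan_hp(table, layout, f"pool:{pool}", size, step)
        scans[f"fst_{pool}"] = scan_fst(table, layout, "genotypes",
                                        f"pool:{pool}", size, step)
    for name, scan in scans.items():
        scan.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False)

    # --- regions ----------------------------------------------------------
    regions: dict[str, pd.DataFrame] = {}
    regions["hp"] = merge_windows(
        flag_windows(scans["hp"], config.hp_threshold, "lower"),
        method="Hp", population="focal")
    regions["hp_extreme"] = merge_windows(
        flag_windows(scans["hp"], config.hp_extreme_threshold, "lower"),
        method="Hp", population="focal")
    regions["tajima"] = merge_windows(
        flag_windows(scans["tajima"], config.tajima_threshold, "lower"),
        method="TajimaD", population="focal")
    for pool in table.pools:
        regions[f"fst_{pool}"] = merge_windows(
            flag_windows(scans[f"fst_{pool}"], config.fst_threshold, "upper"),
            method=f"FST:{pool}", population="focal")
    if truth is not None:
        regions["truth"] = truth
    for name, reg in regions.items():
        write_bed(reg, outdir / f"regions_{name}.bed")

    # --- comparisons ------------------------------------------------------
    comparisons: dict[str, dict] = {}
    pairs = [("hp", "tajima")]
    pairs += [("hp", f"fst_{p}") for p in table.pools]
    if truth is not None:
        pairs += [("truth", "hp"), ("truth", "tajima")]
    for a, b in pairs:
        cmp_ = overlap_regions(regions[a], regions[b])
        comparisons[f"{a}__{b}"] = {
            "n_a": cmp_.n_a, "n_b": cmp_.n_b,
            "n_a_overlapping": cmp_.n_a_overlapping,
            "n_b_overlapping": cmp_.n_b_overlapping,
            "pairs": cmp_.pairs,
        }

    # --- origin -----------------------------------------------------------
    both = regions["hp"]
    if len(regions["tajima"]):
        keep = {i for i, _ in overlap_regions(regions["hp"],
                                              regions["tajima"]).pairs}
        both = regions["hp"].iloc[sorted(keep)] if keep else regions["hp"].iloc[:0]
    origin_rows = []
    for _, reg in both.iterrows():
        call = region_origin(reg, table,
                             wild_pool=config.wild_pool,
                             domestic_pool=config.domestic_pool,
                             params=config.painter,
                             n_donor_haplotypes=config.n_donor_haplotypes,
                             seed=config.seed)
        origin_rows.append(dataclasses.asdict(call))
    origins = pd.DataFrame(origin_rows, columns=[
        "chrom", "start", "end", "fst_vs_domestic", "fst_vs_wild",
        "chunks_domestic", "chunks_wild", "verdict", "reason"])
    origins.to_csv(outdir / "origins.tsv", sep="\t", index=False)

    # --- gene annotation --------------------------------------------------
    genes = None
    if config.annotation_bed is not None:
        annotation = read_bed(config.annotation_bed)
        genes = genes_near(regions["hp"], annotation, config.gene_margin)
        genes.to_csv(outdir / "genes_near_sweeps.tsv", sep="\t", index=False)

    manifest = {
        "feralscan_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_sites": int(table.n_sites),
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    result = PipelineResult(config, scans, regions, comparisons,
                            origins, genes, manifest)
    report(result, outdir)
    return result


def report(result: PipelineResult, outdir=None) -> str:
    """Human-readable run summary; also written as summary.txt/.tsv."""
    lines = [f"feralscan {__version__} run "
             f"(seed={result.config.seed}, config={result.manifest['config_hash']})",
             ""]
    rows = []
    for name, scan in result.scans.items():
        n_valid = int(scan["valid"].sum())
        lines.append(f"scan {name}: {len(scan)} windows, {n_valid} valid")
        rows.append({"item": f"scan_{name}", "count": n_valid})
    lines.append("")
    for name, reg in result.regions.items():
        summ = region_summary(reg)
        lines.append(
            f"regions {name}: {summ['count']} regions, "
            f"median length {summ['median_length']:.0f}, "
            f"max {summ['max_length']:.0f}"
            if summ["count"] else f"regions {name}: 0 regions")
        rows.append({"item": f"regions_{name}", "count": summ["count"]})
    lines.append("")
    for name, cmp_ in result.comparisons.items():
        lines.append(f"overlap {name}: {cmp_['n_a_overlapping']}/{cmp_['n_a']} "
                     f"regions in A overlap one of {cmp_['n_b']} in B")
        rows.append({"item": f"overlap_{name}",
                     "count": cmp_["n_a_overlapping"]})
    lines.append("")
    if len(result.origins):
        for _, o in result.origins.iterrows():
            lines.append(
                f"origin {o['chrom']}:{o['start']}-{o['end']}: {o['verdict']} "
                f"(FSTd={o['fst_vs_domestic']:.3f} FSTw={o['fst_vs_wild']:.3f} "
                f"chunks d={o['chunks_domestic']:.2f} w={o['chunks_wild']:.2f})")
    else:
        lines.append("origin: no regions to assign")
    text = "\n".join(lines) + "\n"
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "summary.txt").write_text(text)
        pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return text
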