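"""Synthetic admixed populations with planted selective sweeps.

The generator emulates the study system every downstream stage needs:

* two diverged source populations (wild-like and domestic-like) whose
  allele frequencies drift apart under the Balding-Nichols model;
* an admixed focal ("feral") population whose phased haplotypes are
  recombinant mosaics of source haplotypes, with ancestry tracts produced
  by a two-state Markov switch process;
* planted sweep intervals of known origin in which a chosen fraction of
  focal haplotypes copy one fixed origin haplotype (hardness 1.0 =
  complete sweep, drastically reduced diversity);
* an observation layer: per-individual genotypes with a small miscall
  rate, and pooled sequencing read counts at low (~5x) depth with
  sequencing error.

Latent panels (exact haplotypes, ancestry tracts, sweep truth) are kept
separate from observed data so recovery tests can compare against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import GenomeLayout, SiteTable, write_vcf

WILD = "wild"
DOMESTIC = "domestic"


@dataclass(frozen=True)
class PlantedSweep:
    """Truth record for one planted sweep (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    origin: str  # WILD or DOMESTIC
    hardness: float = 1.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("sweep start must be < end")
        if self.origin not in (WILD, DOMESTIC):
            raise ValueError(f"origin must be '{WILD}' or '{DOMESTIC}'")
        if not 0.0 < self.hardness <= 1.0:
            raise ValueError("hardness must be in (0, 1]")


@dataclass
class SimParams:
    """Study-condition parameters for the synthetic admixed population.

    Defaults follow the emulated regime: ~23 focal individuals sequenced
    individually, source pools of 8 diploids at ~5x pooled depth, source
    divergence FST ~0.2, a focal population drawing ~80% of its ancestry
    from the domestic-like source over ~30 generations of admixture, and
    about one polymorphic site per kilobase.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_sites: int = 5_000            # per chromosome
    divergence_fst: float = 0.2
    n_wild: int = 8
    n_domestic: int = 8
    n_feral: int = 23
    admixture_prop: float = 0.8     # fraction of feral ancestry from domestic
    n_admix_generations: int = 30
    recomb_rate: float = 1e-8       # per base per generation
    pool_depth: float = 5.0         # mean reads per site per pool
    pool_error: float = 0.002       # per-read miscall probability
    genotype_error: float = 0.005   # per-allele miscall on observed genotypes
    sweeps: list[PlantedSweep] = field(default_factory=list)

    def __post_init__(self):
        for name in ("n_chrom", "chrom_length", "n_sites", "n_wild",
                     "n_domestic", "n_feral", "n_admix_generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("admixture_prop",):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must be in [0, 1)")
        for name in ("recomb_rate", "pool_depth", "pool_error",
                     "genotype_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.sweeps = [s if isinstance(s, PlantedSweep) else PlantedSweep(**s)
                       for s in self.sweeps]
        names = set(self.layout().names)
        seen: dict[str, list[tuple[int, int]]] = {}
        for s in self.sweeps:
            if s.chrom not in names:
                raise ValueError(f"sweep chromosome {s.chrom!r} not simulated")
            if s.end > self.chrom_length:
                raise ValueError("sweep interval outside chromosome bounds")
            for lo, hi in seen.get(s.chrom, []):
                if s.start < hi and lo < s.end:
                    raise ValueError("sweep intervals overlap")
            seen.setdefault(s.chrom, []).append((s.start, s.end))

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chrom))
        return GenomeLayout(names, (self.chrom_length,) * self.n_chrom)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweeps"] = [dataclasses.asdict(s) for s in self.sweeps]
        return d


@dataclass
class SourcePanels:
    """Source allele frequencies and phased source haplotype panels."""

    positions: dict[str, np.ndarray]      # per chrom, sorted unique 0-based
    p_ancestral: dict[str, np.ndarray]
    p_wild: dict[str, np.ndarray]
    p_domestic: dict[str, np.ndarray]
    wild: dict[str, np.ndarray]           # (2*n_wild, n_sites) int8
    domestic: dict[str, np.ndarray]

    def panel(self, origin: str) -> dict[str, np.ndarray]:
        return self.wild if origin == WILD else self.domestic


@dataclass
class FeralPanel:
    """Phased focal haplotypes plus ancestry-tract truth."""

    haplotypes: dict[str, np.ndarray]     # (2*n_feral, n_sites) int8
    # per chrom, per haplotype: list of (start, end, source) base intervals
    ancestry: dict[str, list[list[tuple[int, int, str]]]]
    swept: dict[int, np.ndarray]          # sweep index -> swept haplotype ids


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------


def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Population frequency drawn around the ancestral one with drift fst."""
    if fst < 1e-12:
        return p_anc.copy()
    shape = (1.0 - fst) / fst
    return rng.beta(p_anc * shape, (1.0 - p_anc) * shape)


def simulate_sources(params: SimParams) -> SourcePanels:
    """Draw ancestral/source frequencies and phased source haplotype panels.

    Per site the ancestral frequency is Uniform(0.05, 0.95); wild and
    domestic frequencies are Balding-Nichols draws with drift parameter
    ``divergence_fst``; haplotype alleles are Bernoulli per site.
    """
    rng = _rng(params, 0)
    layout = params.layout()
    out = SourcePanels({}, {}, {}, {}, {}, {})
    for chrom in layout.names:
        pos = np.sort(rng.choice(params.chrom_length, size=params.n_sites,
                                 replace=False)).astype(np.int64)
        p_anc = rng.uniform(0.05, 0.95, size=params.n_sites)
        p_w = _balding_nichols(rng, p_anc, params.divergence_fst)
        p_d = _balding_nichols(rng, p_anc, params.divergence_fst)
        wild = (rng.random((2 * params.n_wild, params.n_sites))
                < p_w[None, :]).astype(np.int8)
        dom = (rng.random((2 * params.n_domestic, params.n_sites))
               < p_d[None, :]).astype(np.int8)
        out.positions[chrom] = pos
        out.p_ancestral[chrom] = p_anc
        out.p_wild[chrom] = p_w
        out.p_domestic[chrom] = p_d
        out.wild[chrom] = wild
        out.domestic[chrom] = dom
    return out


# ---------------------------------------------------------------------------
# feral mosaic + planted sweeps
# ---------------------------------------------------------------------------


def simulate_feral(params: SimParams, sources: SourcePanels) -> FeralPanel:
    """Build the admixed focal panel and overwrite planted sweep intervals.

    Ancestry tracks follow a Markov switch process along each chromosome
    with per-base switch rate ``recomb_rate * n_admix_generations``; at
    each switch the source is domestic with probability ``admixture_prop``
    and a donor haplotype is drawn uniformly from that source panel.
    Planted sweeps then force a ``hardness`` fraction of focal haplotypes
    to copy one fixed origin haplotype across the interval.
    """
    rng = _rng(params, 1)
    layout = params.layout()
    H = 2 * params.n_feral
    lam = params.recomb_rate * params.n_admix_generations
    haps: dict[str, np.ndarray] = {}
    ancestry: dict[str, list] = {}
    for chrom in layout.names:
        pos = sources.positions[chrom]
        n_sites = len(pos)
        p_switch = -np.expm1(-lam * np.diff(pos).astype(float))
        panel = {WILD: sources.wild[chrom], DOMESTIC: sources.domestic[chrom]}
        hmat = np.empty((H, n_sites), dtype=np.int8)
        tracks: list[list[tuple[int, int, str]]] = []
        for h in range(H):
            switches = np.flatnonzero(rng.random(n_sites - 1) < p_switch) + 1
            seg_starts = np.concatenate([[0], switches])
            seg_ends = np.concatenate([switches, [n_sites]])
            track = []
            for k, (s, e) in enumerate(zip(seg_starts, seg_ends)):
                source = DOMESTIC if rng.random() < params.admixture_prop else WILD
                donor = rng.integers(panel[source].shape[0])
                hmat[h, s:e] = panel[source][donor, s:e]
                b_start = 0 if k == 0 else int(pos[s])
                b_end = params.chrom_length if e == n_sites else int(pos[e])
                track.append((b_start, b_end, source))
            tracks.append(_merge_track(track))
        haps[chrom] = hmat
        ancestry[chrom] = tracks

    swept: dict[int, np.ndarray] = {}
    for i, sw in enumerate(params.sweeps):
        pos = sources.positions[sw.chrom]
        in_sweep = (pos >= sw.start) & (pos < sw.end)
        origin_panel = sources.panel(sw.origin)[sw.chrom]
        donor = rng.integers(origin_panel.shape[0])
        k = max(1, int(round(sw.hardness * H)))
        chosen = np.sort(rng.choice(H, size=k, replace=False))
        haps[sw.chrom][np.ix_(chosen, np.flatnonzero(in_sweep))] = \
            origin_panel[donor, in_sweep]
        for h in chosen:
            ancestry[sw.chrom][h] = _splice_track(
                ancestry[sw.chrom][h], sw.start, sw.end, sw.origin)
        swept[i] = chosen
    return FeralPanel(haplotypes=haps, ancestry=ancestry, swept=swept)


def _merge_track(track):
    out = [track[0]]
    for s, e, lab in track[1:]:
        ps, pe, plab = out[-1]
        if lab == plab:
            out[-1] = (ps, e, lab)
        else:
            out.append((s, e, lab))
    return out


def _splice_track(track, start, end, label):
    out = []
    for s, e, lab in track:
        if e <= start or s >= end:
            out.append((s, e, lab))
        else:
            if s < start:
                out.append((s, start, lab))
            if e > end:
                out.append((end, e, lab))
    out.append((start, end, label))
    out.sort()
    return _merge_track(out)


# ---------------------------------------------------------------------------
# observation layer
# ---------------------------------------------------------------------------


def simulate_pool_reads(panel: np.ndarray, pool_depth: float,
                        pool_error: float, rng) -> np.ndarray:
    """Pooled sequencing read counts from a haplotype panel.

    Per site the read count is Poisson(pool_depth) for the whole pool;
    each read samples an allele at the pool frequency and is miscalled
    with probability ``pool_error``.  Returns (n_sites, 2) (ref, alt).
    """
    if pool_depth < 0 or pool_error < 0:
        raise ValueError("pool depth and error must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    freq = panel.mean(axis=0)
    depth = rng.poisson(pool_depth, size=panel.shape[1])
    p_alt_read = freq * (1 - pool_error) + (1 - freq) * pool_error
    alt = rng.binomial(depth, p_alt_read)
    return np.stack([depth - alt, alt], axis=1).astype(np.int64)


def observe(params: SimParams, sources: SourcePanels,
            feral: FeralPanel) -> SiteTable:
    """Emit the observed SiteTable: noisy focal genotypes + pool read counts.

    Focal haplotype alleles are flipped with probability
    ``genotype_error`` (the miscall layer of low-coverage joint calling);
    wild and domestic source panels are observed only through pooled reads.
    Sites monomorphic across all latent panels are dropped.
    """
    rng = _rng(params, 2)
    layout = params.layout()
    rows = []
    hap_blocks = []
    pool_blocks: dict[str, list] = {WILD + "_pool": [], DOMESTIC + "_pool": []}
    for chrom in layout.names:
        pos = sources.positions[chrom]
        fh = feral.haplotypes[chrom]
        flips = rng.random(fh.shape) < params.genotype_error
        obs = (fh ^ flips).astype(np.int8)
        wild_counts = simulate_pool_reads(
            sources.wild[chrom], params.pool_depth, params.pool_error, rng)
        dom_counts = simulate_pool_reads(
            sources.domestic[chrom], params.pool_depth, params.pool_error, rng)
        any_alt = (obs.any(axis=0) | sources.wild[chrom].any(axis=0)
                   | sources.domestic[chrom].any(axis=0))
        all_alt = (obs.all(axis=0) & sources.wild[chrom].all(axis=0)
                   & sources.domestic[chrom].all(axis=0))
        keep = np.flatnonzero(any_alt & ~all_alt)
        for i in keep:
            rows.append((chrom, int(pos[i]) + 1, "A", "C"))
        hap_blocks.append(obs[:, keep].T)
        pool_blocks[WILD + "_pool"].append(wild_counts[keep])
        pool_blocks[DOMESTIC + "_pool"].append(dom_counts[keep])

    haplotypes = np.concatenate(hap_blocks, axis=0)
    genotypes = haplotypes[:, 0::2] + haplotypes[:, 1::2]
    table = SiteTable(
        sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]),
        individual_ids=tuple(f"feral_{i:02d}" for i in range(params.n_feral)),
        genotypes=genotypes.astype(np.int8),
        haplotypes=haplotypes.astype(np.int8),
        pools={name: np.concatenate(blocks, axis=0)
               for name, blocks in pool_blocks.items()},
    )
    table.validate(layout)
    return table


def simulate(params: SimParams):
    """Full generation: sources, feral mosaic and observed SiteTable."""
    sources = simulate_sources(params)
    feral = simulate_feral(params, sources)
    table = observe(params, sources, feral)
    return sources, feral, table


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def sweeps_to_regions(sweeps) -> pd.DataFrame:
    """Planted-sweep truth as a region table (for overlap bookkeeping)."""
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, 1, 0.0, f"truth:{s.origin}", "feral")
         for s in sweeps],
        columns=["chrom", "start", "end", "window_count", "extreme_z",
                 "method", "population"])


def write_fixture(params: SimParams, table: SiteTable, outdir) -> dict:
    """Write VCF + chromosome-length TSV + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = params.layout()
    paths = {
        "vcf": outdir / "variants.vcf",
        "layout": outdir / "chrom_lengths.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(table, layout, paths["vcf"])
    layout.to_tsv(paths["layout"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "params": params.to_dict(),
            "sweeps": [dataclasses.asdict(s) for s in params.sweeps],
            "individuals": list(table.individual_ids),
            "pools": list(table.pools),
        }, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def demo_params(seed: int = 0, sweeps: bool = True) -> SimParams:
    """The bundled study configuration: 2 x 5 Mb chromosomes, ~1 site/kb,
    three planted hardness-1.0 sweeps of 120-200 kb with known origins."""
    planted = [
        PlantedSweep("chr1", 1_000_000, 1_150_000, DOMESTIC),
        PlantedSweep("chr1", 3_500_000, 3_700_000, WILD),
        PlantedSweep("chr2", 2_000_000, 2_120_000, DOMESTIC),
    ] if sweeps else []
    return SimParams(seed=seed, sweeps=planted)
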