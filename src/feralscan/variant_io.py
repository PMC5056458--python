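"""Variant I/O, site filtering and allele-count extraction.

The central container is :class:`SiteTable`: biallelic SNP sites carrying a
diploid-genotype channel for individually sequenced samples and per-pool
read-count channels for pool-sequenced samples.  Every downstream statistic
consumes per-site allele counts pulled from one of these channels.

Coordinate convention: internal coordinates are 0-based half-open
(``pos0``); VCF positions (1-based) are converted at the I/O boundary.
Interval files (BED) are read and written 0-based half-open as usual;
GFF3 gene rows are converted from 1-based inclusive on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing genotype / haplotype allele


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths: the coordinate frame for windowing."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length_of(self, name: str) -> int:
        return self.sizes[name]

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tlength\n")
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# site table
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Filtered biallelic sites with genotype and/or pool read-count channels.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int, as in
        VCF), ``ref``, ``alt``.  Sorted by (chrom in layout order, pos),
        unique positions per chromosome.
    individual_ids:
        Sample names of the individually genotyped (focal) samples.
    genotypes:
        ``(n_sites, n_individuals)`` int8 array of alt-allele dosages
        {0, 1, 2}, ``-1`` for missing; ``None`` if no individuals.
    haplotypes:
        ``(n_sites, 2 * n_individuals)`` int8 array of phased alleles
        {0, 1}, ``-1`` missing; ``None`` when genotypes are unphased.
    pools:
        Mapping pool name -> ``(n_sites, 2)`` int64 array of
        (ref_reads, alt_reads).
    """

    sites: pd.DataFrame
    individual_ids: tuple[str, ...] = ()
    genotypes: np.ndarray | None = None
    haplotypes: np.ndarray | None = None
    pools: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    # -- basic properties ---------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def pos0(self) -> np.ndarray:
        """0-based positions."""
        return self.sites["pos"].to_numpy() - 1

    def channels(self) -> list[str]:
        out = []
        if self.genotypes is not None:
            out.append("genotypes")
        out.extend(f"pool:{name}" for name in self.pools)
        return out

    def validate(self, layout: GenomeLayout | None = None) -> None:
        s = self.sites
        n = len(s)
        if self.genotypes is not None and self.genotypes.shape[0] != n:
            raise ValueError("genotype array does not match site count")
        if self.haplotypes is not None and self.haplotypes.shape[0] != n:
            raise ValueError("haplotype array does not match site count")
        for name, counts in self.pools.items():
            if counts.shape != (n, 2):
                raise ValueError(f"pool {name!r} counts must be (n_sites, 2)")
            if (counts < 0).any():
                raise ValueError(f"pool {name!r} has negative read counts")
        for chrom, grp in s.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not sorted/unique on {chrom}")
            if layout is not None:
                if chrom not in layout:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if pos.max(initial=0) > layout.length_of(chrom):
                    raise ValueError(f"position beyond {chrom} length")

    # -- indexing -----------------------------------------------------------

    def subset(self, index) -> "SiteTable":
        """Return a new SiteTable restricted to the given site index/mask."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SiteTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            individual_ids=self.individual_ids,
            genotypes=None if self.genotypes is None else self.genotypes[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            pools={k: v[idx] for k, v in self.pools.items()},
            meta=dict(self.meta),
        )

    def window_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with 0-based position in [start, end) on chrom."""
        on = self.sites["chrom"].to_numpy() == chrom
        idx = np.flatnonzero(on)
        pos0 = self.sites["pos"].to_numpy()[idx] - 1
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return idx[lo:hi]

    def restrict(self, chrom: str, start: int, end: int) -> "SiteTable":
        return self.subset(self.window_index(chrom, start, end))

    # -- channel access -----------------------------------------------------

    def pool_counts(self, name: str) -> np.ndarray:
        if name not in self.pools:
            raise KeyError(f"unknown pool {name!r}")
        return self.pools[name]


def _parse_channel(table: SiteTable, channel: str):
    """Resolve a channel spec ('genotypes' or 'pool:<name>')."""
    if channel == "genotypes":
        if table.genotypes is None:
            raise KeyError("table has no genotype channel")
        return ("genotypes", None)
    if channel.startswith("pool:"):
        name = channel.split(":", 1)[1]
        if name not in table.pools:
            raise KeyError(f"unknown pool channel {name!r}")
        return ("pool", name)
    raise KeyError(f"unknown channel {channel!r}")


def ref_alt_counts(table: SiteTable, channel: str) -> np.ndarray:
    """Per-site (ref, alt) allele counts for a channel, shape (n_sites, 2).

    For the genotype channel counts are chromosomes of non-missing calls
    (ref = 2*called - sum(dosage)); for a pool channel they are read counts.
    """
    kind, name = _parse_channel(table, channel)
    if kind == "pool":
        return table.pools[name].astype(np.int64)
    g = table.genotypes
    called = (g != MISSING).sum(axis=1)
    alt = np.where(g == MISSING, 0, g).sum(axis=1)
    ref = 2 * called - alt
    return np.stack([ref, alt], axis=1).astype(np.int64)


def allele_counts(table: SiteTable, window=None, channel: str = "genotypes"):
    """Per-site (n_major, n_minor) counts for sites in a window.

    ``window`` is ``(chrom, start, end)`` in 0-based half-open coordinates,
    or ``None`` for all sites.  The major allele is the more frequent allele
    at that site in that channel; exact 50/50 ties break to the ref allele.
    """
    if window is not None:
        table = table.restrict(*window)
    ra = ref_alt_counts(table, channel)
    major = ra.max(axis=1)
    minor = ra.min(axis=1)
    return major, minor


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def read_variants(
    vcf_path,
    layout: GenomeLayout,
    individuals: tuple[str, ...] | list[str] | None = None,
    pools: tuple[str, ...] | list[str] = (),
) -> SiteTable:
    """Read a VCF into a SiteTable.

    ``individuals`` and ``pools`` declare sample roles.  Individuals
    contribute the genotype (GT) channel; pools contribute read-count (AD)
    channels.  When ``individuals`` is None, every sample not named in
    ``pools`` is treated as an individual.  Multiallelic and non-SNP records
    are skipped, with counts logged and recorded in ``table.meta``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    pools = list(pools)
    for p in pools:
        if p not in samples:
            raise ValueError(f"pool sample {p!r} not in VCF")
    if individuals is None:
        individuals = [s for s in samples if s not in pools]
    else:
        individuals = list(individuals)
        for s in individuals:
            if s not in samples:
                raise ValueError(f"individual sample {s!r} not in VCF")
    ind_idx = [samples.index(s) for s in individuals]
    pool_idx = {p: samples.index(p) for p in pools}

    rows = []
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    pool_rows: dict[str, list] = {p: [] for p in pools}
    n_multi = 0
    n_nonsnp = 0
    all_phased = True

    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_nonsnp += 1
            continue
        if v.CHROM not in layout:
            raise ValueError(f"chromosome {v.CHROM!r} not in layout")
        if v.POS > layout.length_of(v.CHROM):
            raise ValueError(
                f"position {v.CHROM}:{v.POS} beyond chromosome length")
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))

        if ind_idx:
            gts = v.genotypes  # [allele0, allele1, phased] per sample
            dos = np.empty(len(ind_idx), dtype=np.int8)
            hap = np.empty(2 * len(ind_idx), dtype=np.int8)
            for k, i in enumerate(ind_idx):
                a0, a1 = gts[i][0], gts[i][1]
                phased = bool(gts[i][2])
                if a0 < 0 or a1 < 0:
                    dos[k] = MISSING
                    hap[2 * k] = hap[2 * k + 1] = MISSING
                else:
                    dos[k] = a0 + a1
                    hap[2 * k], hap[2 * k + 1] = a0, a1
                    if not phased and a0 != a1:
                        all_phased = False
            geno_rows.append(dos)
            hap_rows.append(hap)

        if pools:
            ad = v.format("AD")
            for p, i in pool_idx.items():
                if ad is None:
                    pool_rows[p].append((0, 0))
                else:
                    r, a = int(ad[i][0]), int(ad[i][1])
                    pool_rows[p].append((max(r, 0), max(a, 0)))

    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    if n_nonsnp:
        logger.info("skipped %d non-SNP records", n_nonsnp)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    order = {name: i for i, name in enumerate(layout.names)}
    genotypes = (np.array(geno_rows, dtype=np.int8) if rows else
                 np.zeros((0, len(ind_idx)), dtype=np.int8)) if ind_idx else None
    haplotypes = (np.array(hap_rows, dtype=np.int8)
                  if ind_idx and rows and all_phased else None)
    pool_arrays = {p: np.array(pool_rows[p], dtype=np.int64).reshape(-1, 2)
                   for p in pools}
    if len(sites):
        perm = np.lexsort((sites["pos"].to_numpy(),
                           sites["chrom"].map(order).to_numpy()))
        sites = sites.iloc[perm].reset_index(drop=True)
        if genotypes is not None:
            genotypes = genotypes[perm]
        if haplotypes is not None:
            haplotypes = haplotypes[perm]
        pool_arrays = {p: a[perm] for p, a in pool_arrays.items()}
    table = SiteTable(
        sites=sites,
        individual_ids=tuple(individuals),
        genotypes=genotypes,
        haplotypes=haplotypes,
        pools=pool_arrays,
        meta={"skipped_multiallelic": n_multi, "skipped_non_snp": n_nonsnp},
    )
    table.validate(layout)
    return table


def write_vcf(table: SiteTable, layout: GenomeLayout, path) -> None:
    """Write a SiteTable as a minimal standards-conformant VCF 4.2 text file.

    Individuals get phased GT (from the haplotype channel when present);
    pools are emitted as samples with missing GT and an AD field holding
    (ref_reads, alt_reads).
    """
    ind = list(table.individual_ids)
    pools = list(table.pools)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralscan\n")
        for name, length in zip(layout.names, layout.lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT"] + ind + pools
        fh.write("\t".join(cols) + "\n")
        s = table.sites
        chroms = s["chrom"].to_numpy()
        poss = s["pos"].to_numpy()
        refs = s["ref"].to_numpy()
        alts = s["alt"].to_numpy()
        for i in range(table.n_sites):
            fields = [chroms[i], str(poss[i]), ".", refs[i], alts[i],
                      ".", "PASS", ".", "GT:AD"]
            for k in range(len(ind)):
                if table.haplotypes is not None:
                    a0 = table.haplotypes[i, 2 * k]
                    a1 = table.haplotypes[i, 2 * k + 1]
                    gt = "./." if a0 < 0 or a1 < 0 else f"{a0}|{a1}"
                else:
                    d = table.genotypes[i, k]
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(int(d), "./.")
                fields.append(f"{gt}:.")
            for p in pools:
                r, a = table.pools[p][i]
                fields.append(f"./.:{r},{a}")
            fh.write("\t".join(map(str, fields)) + "\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_sites(
    table: SiteTable,
    min_alt_support: int = 2,
    min_complete: float = 0.8,
) -> SiteTable:
    """Apply the variant support / completeness filters, per channel.

    Genotype channel: the variant (alt) allele must be carried by at least
    ``min_alt_support`` chromosomes across the focal sample, and at least a
    ``min_complete`` fraction of individuals must be called.  Pool channels:
    the alt allele must be supported by at least ``min_alt_support`` reads
    summed over all pools.

    Channels are filtered separately: a failing channel is masked at that
    site (genotypes set missing; pool counts zeroed, which downstream layers
    treat as "no information"); sites failing every present channel are
    dropped.  The operation is idempotent.
    """
    if min_alt_support < 0:
        raise ValueError("min_alt_support must be >= 0")
    if not 0.0 <= min_complete <= 1.0:
        raise ValueError("min_complete must be in [0, 1]")

    n = table.n_sites
    any_channel = np.zeros(n, dtype=bool)
    out = table.subset(np.arange(n))  # deep-ish copy of arrays via fancy index

    if out.genotypes is not None and out.genotypes.shape[1] > 0:
        g = out.genotypes
        called = (g != MISSING).sum(axis=1)
        alt = np.where(g == MISSING, 0, g).sum(axis=1)
        complete = called / g.shape[1]
        ok = (alt >= min_alt_support) & (complete >= min_complete)
        g[~ok] = MISSING
        if out.haplotypes is not None:
            out.haplotypes[~ok] = MISSING
        any_channel |= ok
        n_geno_fail = int((~ok).sum())
        if n_geno_fail:
            logger.info("genotype channel: masked %d sites", n_geno_fail)
    if out.pools:
        total_alt = sum(c[:, 1] for c in out.pools.values())
        ok = total_alt >= min_alt_support
        for name in out.pools:
            out.pools[name][~ok] = 0
        any_channel |= ok
        n_pool_fail = int((~ok).sum())
        if n_pool_fail:
            logger.info("pool channels: masked %d sites", n_pool_fail)
    if out.genotypes is None and not out.pools:
        any_channel[:] = True

    out = out.subset(any_channel)
    out.meta["filter_dropped"] = int(n - out.n_sites)
    return out


# ---------------------------------------------------------------------------
# interval files
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) into chrom/start/end/name columns."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    if "name" not in df.columns:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name"]]


def _gff_name(attributes: str) -> str | None:
    fields = dict(kv.split("=", 1) for kv in attributes.strip().split(";")
                  if "=" in kv)
    for key in ("Name", "gene_name", "gene_id", "ID"):
        if key in fields:
            return fields[key]
    return None


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from a GFF3 file (converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            name = _gff_name(parts[8]) or f"{parts[0]}:{parts[3]}"
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(regions: pd.DataFrame, path, score_col: str | None = None) -> None:
    """Write a region table as BED (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("# coords: 0-based half-open\n")
        for i, row in regions.reset_index(drop=True).iterrows():
            name = row.get("method", row.get("name", f"region_{i}"))
            score = row.get(score_col, 0) if score_col else row.get("extreme_z", 0)
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{name}\t{score:.4f}\n")
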