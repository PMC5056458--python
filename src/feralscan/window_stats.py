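"""Windowed genome-scan statistics and their genome-wide Z-scores.

Three statistics are computed in sliding windows (default 40 kb with 20 kb
step) over a :class:`~feralscan.variant_io.SiteTable`:

* pooled heterozygosity ``Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2``
  over per-site major/minor allele (or read) counts;
* Tajima's D from genotype dosages, folded (no ancestral polarisation);
* the Weir-Cockerham method-of-moments FST, treating each window as a locus
  (ratio of summed variance components).

Each scan is standardized genome-wide to Z-scores (``ZHp``, ``ZTajima``,
``ZFST``) over its valid windows; windows with fewer than three informative
variants are flagged invalid and get no Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenomeLayout, SiteTable, ref_alt_counts

MIN_VARIANTS = 3  # windows with fewer informative variants are not considered


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(layout: GenomeLayout, size: int = 40_000,
                 step: int = 20_000) -> pd.DataFrame:
    """Sliding windows per chromosome; trailing partial windows are dropped.

    Starts run 0, step, 2*step, ... with ``start + size <= length``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not 0 < step <= size:
        raise ValueError("step must satisfy 0 < step <= size")
    rows = []
    for chrom, length in zip(layout.names, layout.lengths):
        starts = np.arange(0, length - size + 1, step, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(s + size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_site_slices(pos0: np.ndarray, starts: np.ndarray,
                        ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(lo, hi) index pairs of sites in each [start, end) window."""
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi


def _window_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Per-window sums of a per-site array via prefix sums."""
    c = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])
    return c[hi] - c[lo]


# ---------------------------------------------------------------------------
# pooled heterozygosity
# ---------------------------------------------------------------------------


def pooled_heterozygosity(major: np.ndarray, minor: np.ndarray) -> float:
    """Hp for one window from per-site major/minor counts.

    Returns NaN when the window has no counted alleles.
    """
    smaj = float(np.sum(major))
    smin = float(np.sum(minor))
    tot = smaj + smin
    if tot == 0:
        return float("nan")
    return 2.0 * smaj * smin / tot**2


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaConstants:
    """Normalising constants for Tajima's D at a given haplotype count n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("need at least 2 haplotypes")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(genotypes: np.ndarray) -> float:
    """Tajima's D for one window of diploid alt-dosage genotypes.

    ``genotypes`` is (n_sites, n_individuals), dosages {0,1,2}, -1 missing.
    The haplotype count for the normalising constants is 2 * n_individuals;
    per-site pairwise diversity uses the site's called chromosome count.
    Returns NaN when fewer than MIN_VARIANTS sites segregate.  The n = 2
    degenerate case (numerator identically zero) returns 0.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] < 1:
        raise ValueError("genotypes must be (n_sites, n_individuals)")
    n = 2 * g.shape[1]
    called = 2 * (g != MISSING).sum(axis=1)
    j = np.where(g == MISSING, 0, g).sum(axis=1)  # alt allele count per site
    seg = (j > 0) & (j < called)
    s_count = int(seg.sum())
    if s_count < MIN_VARIANTS and n > 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(called > 1,
                           2.0 * j * (called - j) / (called * (called - 1.0)),
                           0.0)
    theta_pi = float(pi_site.sum())
    const = TajimaConstants.from_n(n)
    theta_w = s_count / const.a1
    num = theta_pi - theta_w
    var = const.e1 * s_count + const.e2 * s_count * (s_count - 1)
    if var <= 0:
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


def diploid_fst_components(g1: np.ndarray, g2: np.ndarray):
    """Per-site Weir-Cockerham variance components for two diploid samples.

    Returns ``(a, b, c)`` arrays: among-population, among-individual-within
    and within-individual components.  Sites where either population has no
    called individual get NaN components.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    r = 2.0
    n1 = (g1 != MISSING).sum(axis=1).astype(float)
    n2 = (g2 != MISSING).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(g1 == MISSING, 0, g1).sum(axis=1) / (2 * n1)
        p2 = np.where(g2 == MISSING, 0, g2).sum(axis=1) / (2 * n2)
        h1 = (g1 == 1).sum(axis=1) / n1  # observed heterozygote fraction
        h2 = (g2 == 1).sum(axis=1) / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def haploid_fst_components(counts1: np.ndarray, counts2: np.ndarray):
    """Per-site Weir-Cockerham components treating alleles as haploid samples.

    ``counts1``/``counts2`` are (n_sites, 2) (ref, alt) allele or read
    counts.  Used when at least one side is a pool channel (read counts
    carry no individual-level heterozygosity); returns ``(a, d)`` with
    ``a`` the among-population component and ``d`` the total (``a`` plus
    the within-population mean square).
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = c1[:, 1] / n1
        p2 = c2[:, 1] / n2
        ntot = n1 + n2
        pbar = (c1[:, 1] + c2[:, 1]) / ntot
        nc = ntot - (n1**2 + n2**2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        a = (msp - msg) / nc
        d = a + msg
    bad = (n1 < 1) | (n2 < 1) | (ntot < 3) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    d = np.where(bad, np.nan, d)
    return a, d


def weir_cockerham_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Window FST as the ratio of summed per-site components.

    ``num``/``den`` are per-site numerator (a) and total (a+b+c) components;
    NaN sites are skipped.  Returns NaN when no informative site remains or
    the summed denominator is not positive.
    """
    ok = np.isfinite(num) & np.isfinite(den)
    if not ok.any():
        return float("nan")
    s_den = float(den[ok].sum())
    if s_den <= 0:
        return float("nan")
    return float(num[ok].sum()) / s_den


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize(values: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Genome-wide Z-scores over valid windows: z = (x - mean) / sd.

    Sample standard deviation (n-1 divisor).  Invalid windows get NaN.
    Raises on degenerate scans (fewer than 2 valid windows or sd == 0).
    """
    x = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(x)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(x)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid windows to standardize")
    mu = x[valid].mean()
    sd = x[valid].std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate scan: zero standard deviation")
    z = np.full_like(x, np.nan, dtype=float)
    z[valid] = (x[valid] - mu) / sd
    return z


# ---------------------------------------------------------------------------
# scans over a SiteTable
# ---------------------------------------------------------------------------


def _per_chrom(table: SiteTable, windows: pd.DataFrame):
    """Yield (chrom, window sub-frame, site index array) per chromosome."""
    chroms = table.sites["chrom"].to_numpy()
    for chrom, wsub in windows.groupby("chrom", sort=False):
        idx = np.flatnonzero(chroms == chrom)
        yield chrom, wsub, idx


def _assemble(windows: pd.DataFrame, stat: str, n_var: np.ndarray,
              raw: np.ndarray, min_variants: int) -> pd.DataFrame:
    out = windows.copy().reset_index(drop=True)
    out["n_variants"] = n_var.astype(int)
    out["raw"] = raw
    out["valid"] = (n_var >= min_variants) & np.isfinite(raw)
    out["z"] = standardize(raw, out["valid"].to_numpy())
    out["stat"] = stat
    return out


def scan_hp(table: SiteTable, layout: GenomeLayout, channel: str = "genotypes",
            size: int = 40_000, step: int = 20_000,
            min_variants: int = MIN_VARIANTS) -> pd.DataFrame:
    """Pooled-heterozygosity scan with genome-wide ZHp."""
    windows = make_windows(layout, size, step)
    ra = ref_alt_counts(table, channel)
    major = ra.max(axis=1).astype(float)
    minor = ra.min(axis=1).astype(float)
    informative = (major + minor) > 0
    n_var = np.zeros(len(windows))
    raw = np.full(len(windows), np.nan)
    pos_all = table.pos0
    for chrom, wsub, idx in _per_chrom(table, windows):
        lo, hi = _window_site_slices(pos_all[idx], wsub["start"].to_numpy(),
                                     wsub["end"].to_numpy())
        wi = wsub.index.to_numpy()
        n_var[wi] = _window_sums(informative[idx], lo, hi)
        smaj = _window_sums(major[idx], lo, hi)
        smin = _window_sums(minor[idx], lo, hi)
        tot = smaj + smin
        with np.errstate(divide="ignore", invalid="ignore"):
            raw[wi] = np.where(tot > 0, 2.0 * smaj * smin / tot**2, np.nan)
    return _assemble(windows, "Hp", n_var, raw, min_variants)


def scan_tajima(table: SiteTable, layout: GenomeLayout,
                size: int = 40_000, step: int = 20_000,
                min_variants: int = MIN_VARIANTS) -> pd.DataFrame:
    """Tajima's D scan on the genotype channel with genome-wide ZTajima.

    Validity requires at least ``min_variants`` segregating sites in the
    window (the uniform three-variant rule).
    """
    g = table.genotypes
    if g is None:
        raise ValueError("Tajima's D requires the genotype channel")
    windows = make_windows(layout, size, step)
    n = 2 * g.shape[1]
    const = TajimaConstants.from_n(n)
    called = 2 * (g != MISSING).sum(axis=1)
    j = np.where(g == MISSING, 0, g).sum(axis=1)
    seg = ((j > 0) & (j < called)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(called > 1,
                           2.0 * j * (called - j) / (called * (called - 1.0)),
                           0.0)
    n_var = np.zeros(len(windows))
    raw = np.full(len(windows), np.nan)
    pos_all = table.pos0
    for chrom, wsub, idx in _per_chrom(table, windows):
        lo, hi = _window_site_slices(pos_all[idx], wsub["start"].to_numpy(),
                                     wsub["end"].to_numpy())
        wi = wsub.index.to_numpy()
        s = _window_sums(seg[idx], lo, hi)
        tpi = _window_sums(pi_site[idx], lo, hi)
        n_var[wi] = s
        theta_w = s / const.a1
        var = const.e1 * s + const.e2 * s * (s - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(var > 0, (tpi - theta_w) / np.sqrt(var), np.nan)
        if n == 2:
            d = np.where(s > 0, 0.0, np.nan)
        raw[wi] = d
    return _assemble(windows, "TajimaD", n_var, raw, min_variants)


def scan_fst(table: SiteTable, layout: GenomeLayout, channel1: str,
             channel2: str, size: int = 40_000, step: int = 20_000,
             min_variants: int = MIN_VARIANTS,
             individuals1: np.ndarray | None = None,
             individuals2: np.ndarray | None = None) -> pd.DataFrame:
    """Weir-Cockerham FST scan between two channels with genome-wide ZFST.

    When both channels are genotype channels (possible via ``individuals1``
    / ``individuals2`` column index subsets of the genotype matrix) the
    diploid estimator with a/b/c components is used; as soon as a pool
    channel is involved both sides are collapsed to allele counts and the
    haploid-reads variant is used.
    """
    windows = make_windows(layout, size, step)

    def geno_cols(ind):
        g = table.genotypes
        if g is None:
            raise ValueError("no genotype channel in table")
        return g if ind is None else g[:, ind]

    diploid = channel1 == "genotypes" and channel2 == "genotypes"
    if diploid:
        a, b, c = diploid_fst_components(geno_cols(individuals1),
                                         geno_cols(individuals2))
        num, den = a, a + b + c
    else:
        def side(channel, ind):
            if channel == "genotypes":
                g = geno_cols(ind)
                calls = (g != MISSING).sum(axis=1)
                alt = np.where(g == MISSING, 0, g).sum(axis=1)
                return np.stack([2 * calls - alt, alt], axis=1)
            return table.pool_counts(channel.split(":", 1)[1])

        num, den = haploid_fst_components(side(channel1, individuals1),
                                          side(channel2, individuals2))
    informative = np.isfinite(num) & np.isfinite(den)
    n_var = np.zeros(len(windows))
    raw = np.full(len(windows), np.nan)
    pos_all = table.pos0
    num_f = np.where(informative, num, 0.0)
    den_f = np.where(informative, den, 0.0)
    for chrom, wsub, idx in _per_chrom(table, windows):
        lo, hi = _window_site_slices(pos_all[idx], wsub["start"].to_numpy(),
                                     wsub["end"].to_numpy())
        wi = wsub.index.to_numpy()
        n_var[wi] = _window_sums(informative[idx], lo, hi)
        s_num = _window_sums(num_f[idx], lo, hi)
        s_den = _window_sums(den_f[idx], lo, hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw[wi] = np.where(s_den > 0, s_num / s_den, np.nan)
    label = f"FST:{channel1}|{channel2}"
    return _assemble(windows, label, n_var, raw, min_variants)
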