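"""Turn Z-scored window scans into sweep regions and compare region sets.

Flagged windows (strict threshold on the Z-score tail) are merged when they
overlap or abut into candidate sweep regions; region sets from different
statistics or populations are intersected by any-shared-base overlap, and
genes are attached when they fall inside a region or within a margin
(default 40 kb) of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end", "window_count", "extreme_z",
                  "method", "population"]


def flag_windows(scan: pd.DataFrame, threshold: float,
                 tail: str = "lower") -> pd.DataFrame:
    """Windows whose Z passes a strict threshold in the given tail.

    ``tail='lower'`` keeps z < threshold, ``'upper'`` keeps z > threshold.
    Only valid windows are considered.  Comparisons are strict, so a window
    at exactly the threshold is not flagged.
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if (tail == "lower" and threshold > 0) or (tail == "upper" and threshold < 0):
        warnings.warn(f"threshold {threshold} has unusual sign for {tail} tail",
                      stacklevel=2)
    if len(scan) == 0:
        return scan.copy()
    z = scan["z"]
    keep = scan["valid"] & (z < threshold if tail == "lower" else z > threshold)
    return scan[keep.fillna(False)].copy()


def merge_windows(flagged: pd.DataFrame, method: str = "",
                  population: str = "") -> pd.DataFrame:
    """Merge overlapping-or-abutting flagged windows into sweep regions.

    Under the default 40 kb / 20 kb-step windows this merges consecutive
    window indices; with non-default steps "consecutive" still means
    coordinate-adjacent.  Each region records its member-window count and
    the most extreme member Z (largest absolute value, signed).
    """
    if len(flagged) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    f = flagged.sort_values(["chrom", "start"], kind="stable")
    rows = []
    cur = None
    for t in f.itertuples(index=False):
        z = float(t.z) if "z" in f.columns else 0.0
        if cur is not None and t.chrom == cur["chrom"] and t.start <= cur["end"]:
            cur["end"] = max(cur["end"], int(t.end))
            cur["window_count"] += 1
            if abs(z) > abs(cur["extreme_z"]):
                cur["extreme_z"] = z
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": t.chrom, "start": int(t.start), "end": int(t.end),
                   "window_count": 1, "extreme_z": z,
                   "method": method, "population": population}
    rows.append(cur)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def region_summary(regions: pd.DataFrame) -> dict:
    """Count, median and maximum region length (bases).

    The median of an even-count list is the mean of the central pair.
    Empty input yields count 0 with undefined (NaN) summaries.
    """
    if len(regions) == 0:
        return {"count": 0, "median_length": float("nan"),
                "max_length": float("nan")}
    lengths = (regions["end"] - regions["start"]).to_numpy()
    return {"count": int(len(lengths)),
            "median_length": float(np.median(lengths)),
            "max_length": float(lengths.max())}


@dataclass
class RegionSetComparison:
    """Overlap bookkeeping between two region sets (any shared base)."""

    n_a: int
    n_b: int
    n_a_overlapping: int  # regions in A overlapping >= 1 region in B
    n_b_overlapping: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def _intersects(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end  # half-open intervals


def overlap_regions(a: pd.DataFrame, b: pd.DataFrame) -> RegionSetComparison:
    """Compare two region sets by half-open interval intersection.

    A pair overlaps when the intervals share at least one base; abutting
    half-open intervals do not overlap.
    """
    pairs = []
    a_ = a.reset_index(drop=True)
    b_ = b.reset_index(drop=True)
    for i, ra in a_.iterrows():
        for j, rb in b_.iterrows():
            if ra["chrom"] == rb["chrom"] and _intersects(
                    ra["start"], ra["end"], rb["start"], rb["end"]):
                pairs.append((i, j))
    return RegionSetComparison(
        n_a=len(a_), n_b=len(b_),
        n_a_overlapping=len({i for i, _ in pairs}),
        n_b_overlapping=len({j for _, j in pairs}),
        pairs=pairs,
    )


def genes_near(regions: pd.DataFrame, annotation: pd.DataFrame,
               margin: int = 40_000) -> pd.DataFrame:
    """Genes inside each region or within ``margin`` bases of it.

    ``annotation`` has chrom/start/end/name columns (0-based half-open).
    Output rows carry the region index, gene name and a tag: ``within``
    when the gene intersects the region itself, ``margin`` when it only
    intersects the margin-expanded region.  Genes on chromosomes absent
    from the region set are simply never matched; annotation rows whose
    chromosome matches no region chromosome trigger a warning.
    """
    regions = regions.reset_index(drop=True)
    known = set(regions["chrom"])
    unknown = set(annotation["chrom"]) - known
    if unknown and len(regions):
        warnings.warn(f"annotation chromosomes not in region set: "
                      f"{sorted(unknown)}", stacklevel=2)
    rows = []
    for i, r in regions.iterrows():
        genes = annotation[annotation["chrom"] == r["chrom"]]
        for _, g in genes.iterrows():
            if _intersects(r["start"], r["end"], g["start"], g["end"]):
                rows.append((i, g["name"], "within"))
            elif _intersects(r["start"] - margin, r["end"] + margin,
                             g["start"], g["end"]):
                rows.append((i, g["name"], "margin"))
    return pd.DataFrame(rows, columns=["region", "gene", "tag"])
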