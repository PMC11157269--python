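"""Hi-C read-pair filtering cascade and anchor binning.

The cascade applies, in order: uniqueness, positional de-duplication,
trans separation, restriction-fragment assignment, same-fragment removal,
and orientation/distance filtering of close inward/outward pairs.  The
surviving inward, outward, and same-strand pairs are merged as cis pairs.

Distances for the inward/outward rules are measured between the midpoints of
the assigned restriction fragments (the symmetric choice of reference point).
De-duplication keys on (chrom1, pos1, chrom2, pos2) ignoring strand, keeping
the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DigestIndex",
    "FilterConfig",
    "FilterQC",
    "FilteredPairs",
    "assign_fragment",
    "classify_orientation",
    "filter_pairs",
    "bin_to_anchors",
    "find_motif_sites",
]

DISPOSITIONS = (
    "non_unique",
    "positional_duplicate",
    "trans_kept",
    "same_fragment",
    "inward_close",
    "outward_close",
    "cis_kept",
)


def find_motif_sites(seq: str, motif: str = "GANTC") -> np.ndarray:
    """0-based start positions of a motif (N = any base) in a sequence."""
    seq = seq.upper()
    k = len(motif)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(m == "N" or m == s for m, s in zip(motif, seq[i : i + k])):
            hits.append(i)
    return np.asarray(hits, dtype=np.int64)


@dataclass
class DigestIndex:
    """Sorted restriction cut positions per chromosome.

    Fragments are the half-open intervals between consecutive boundaries;
    boundary arrays always start at 0 and end at the chromosome length.
    """

    boundaries: dict[str, np.ndarray]

    @classmethod
    def from_cuts(
        cls, cuts: Mapping[str, Iterable[int]], chrom_sizes: Mapping[str, int]
    ) -> "DigestIndex":
        boundaries = {}
        for chrom, size in chrom_sizes.items():
            arr = np.asarray(sorted(set(cuts.get(chrom, []))), dtype=np.int64)
            arr = arr[(arr > 0) & (arr < size)]
            boundaries[chrom] = np.concatenate([[0], arr, [size]])
        return cls(boundaries=boundaries)

    def chrom_length(self, chrom: str) -> int:
        return int(self.boundaries[chrom][-1])

    def n_fragments(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def midpoints(self, chrom: str) -> np.ndarray:
        b = self.boundaries[chrom]
        return (b[:-1] + b[1:]) / 2.0

    def assign(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | int:
        """Fragment index containing ``pos`` (half-open, binary search)."""
        if chrom not in self.boundaries:
            raise KeyError(f"unknown chromosome {chrom!r} in digest")
        b = self.boundaries[chrom]
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if (pos_arr < 0).any() or (pos_arr >= b[-1]).any():
            bad = pos_arr[(pos_arr < 0) | (pos_arr >= b[-1])][0]
            raise ValueError(f"position {bad} outside chromosome {chrom} [0, {b[-1]})")
        frag = np.searchsorted(b, pos_arr, side="right") - 1
        return frag if np.ndim(pos) else int(frag[0])


def assign_fragment(chrom: str, pos: int, digest: DigestIndex) -> int:
    """Index of the restriction fragment containing ``pos`` on ``chrom``."""
    return digest.assign(chrom, pos)


def classify_orientation(strand1: str, strand2: str) -> str:
    """Orientation class of a cis pair with mates ordered by position."""
    if strand1 == "+" and strand2 == "-":
        return "inward"
    if strand1 == "-" and strand2 == "+":
        return "outward"
    return "same_strand"


@dataclass
class FilterConfig:
    inward_min_distance: int = 1000
    outward_min_distance: int = 5000
    anchor_resolution: int = 5000

    def __post_init__(self):
        if self.inward_min_distance <= 0 or self.outward_min_distance <= 0:
            raise ValueError("distance thresholds must be positive")
        if self.anchor_resolution <= 0:
            raise ValueError("anchor_resolution must be positive")


@dataclass
class FilterQC:
    """Per-disposition tallies; dispositions partition the input."""

    counts: dict[str, int] = field(default_factory=dict)
    dispositions: pd.Series | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"disposition": list(self.counts), "count": list(self.counts.values())}
        )


@dataclass
class FilteredPairs:
    cis: pd.DataFrame
    trans: pd.DataFrame


def order_mates(df: pd.DataFrame) -> pd.DataFrame:
    """Order mates so (chrom1, pos1) <= (chrom2, pos2) lexicographically."""
    df = df.copy()
    swap = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"])
    )
    if swap.any():
        cols = [["chrom1", "chrom2"], ["pos1", "pos2"], ["strand1", "strand2"]]
        for a, b in cols:
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def filter_pairs(
    pairs: pd.DataFrame,
    digest: DigestIndex,
    cfg: FilterConfig | None = None,
) -> tuple[FilteredPairs, FilterQC]:
    """Apply the full filtering cascade to a read-pair table.

    Returns the surviving cis and trans pairs plus a QC table whose
    disposition counts partition the input.  The per-record disposition
    series is attached to the QC object for auditing.
    """
    cfg = cfg or FilterConfig()
    df = order_mates(pairs.reset_index(drop=True))
    n = len(df)
    disp = np.full(n, "cis_kept", dtype=object)

    if "unique" in df.columns:
        non_unique = ~df["unique"].astype(bool).to_numpy()
    else:
        non_unique = np.zeros(n, dtype=bool)
    disp[non_unique] = "non_unique"
    alive = ~non_unique

    # positional de-duplication among unique pairs, strand ignored, keep first
    sub = df.loc[alive, ["chrom1", "pos1", "chrom2", "pos2"]]
    dup = sub.duplicated(keep="first").to_numpy()
    dup_idx = sub.index[dup]
    disp[dup_idx] = "positional_duplicate"
    alive[dup_idx] = False

    trans = alive & (df["chrom1"] != df["chrom2"]).to_numpy()
    disp[trans] = "trans_kept"
    alive &= ~trans

    # fragment assignment per chromosome for the remaining cis pairs
    frag1 = np.full(n, -1, dtype=np.int64)
    frag2 = np.full(n, -1, dtype=np.int64)
    mid1 = np.full(n, np.nan)
    mid2 = np.full(n, np.nan)
    for chrom in df.loc[alive, "chrom1"].unique():
        sel = alive & (df["chrom1"] == chrom).to_numpy()
        mids = digest.midpoints(chrom)
        f1 = digest.assign(chrom, df.loc[sel, "pos1"].to_numpy())
        f2 = digest.assign(chrom, df.loc[sel, "pos2"].to_numpy())
        frag1[sel] = f1
        frag2[sel] = f2
        mid1[sel] = mids[f1]
        mid2[sel] = mids[f2]

    same_frag = alive & (frag1 == frag2)
    disp[same_frag] = "same_fragment"
    alive &= ~same_frag

    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    dist = np.abs(mid2 - mid1)
    inward = alive & (s1 == "+") & (s2 == "-")
    outward = alive & (s1 == "-") & (s2 == "+")
    inward_close = inward & ~(dist > cfg.inward_min_distance)
    outward_close = outward & ~(dist > cfg.outward_min_distance)
    disp[inward_close] = "inward_close"
    disp[outward_close] = "outward_close"
    alive &= ~(inward_close | outward_close)

    disp_series = pd.Series(disp, name="disposition")
    counts = {k: int((disp == k).sum()) for k in DISPOSITIONS}
    qc = FilterQC(counts=counts, dispositions=disp_series)

    cis = df.loc[alive].copy()
    cis["fragment1"] = frag1[alive]
    cis["fragment2"] = frag2[alive]
    trans_df = df.loc[trans].copy()
    return FilteredPairs(cis=cis, trans=trans_df), qc


def bin_to_anchors(cis: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Aggregate cis pairs onto unordered anchor-bin pairs.

    Each mate maps to ``floor(pos / resolution)``; counts are summed per
    (chrom, bin1, bin2) with bin1 <= bin2.  The total count equals the number
    of input pairs.
    """
    if len(cis) == 0:
        return pd.DataFrame(columns=["chrom", "bin1", "bin2", "count"])
    b1 = (cis["pos1"] // resolution).to_numpy(dtype=np.int64)
    b2 = (cis["pos2"] // resolution).to_numpy(dtype=np.int64)
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    out = (
        pd.DataFrame({"chrom": cis["chrom1"].to_numpy(), "bin1": lo, "bin2": hi})
        .groupby(["chrom", "bin1", "bin2"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out
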