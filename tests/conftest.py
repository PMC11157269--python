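import numpy as np
import pandas as pd
import pytest

from hicdelta.pairs import DigestIndex


@pytest.fixture
def hand_digest():
    """Small two-chromosome digest with known fragment midpoints.

    chr1 fragments: [0,1000) [1000,1600) [1600,2000) [2000,10000) [10000,20000)
    [20000,30000) [30000,40000) [40000,60000) [60000,80000) [80000,100000)
    with midpoints 500, 1300, 1800, 6000, 15000, 25000, 35000, 50000, 70000,
    90000.
    """
    cuts = {
        "chr1": [1000, 1600, 2000, 10000, 20000, 30000, 40000, 60000, 80000],
        "chr2": [25000],
    }
    sizes = {"chr1": 100_000, "chr2": 50_000}
    return DigestIndex.from_cuts(cuts, sizes)


def make_pair(chrom1, pos1, s1, chrom2, pos2, s2, unique=True, rid="r"):
    return {
        "readID": rid,
        "chrom1": chrom1,
        "pos1": pos1,
        "chrom2": chrom2,
        "pos2": pos2,
        "strand1": s1,
        "strand2": s2,
        "unique": unique,
    }


@pytest.fixture
def hand_pairs():
    """Ten pairs exercising every cascade rule exactly once (hand-traced).

    Expected dispositions in order:
      1 non_unique, 2 cis_kept, 3 positional_duplicate (of 2), 4 trans_kept,
      5 same_fragment, 6 inward_close (midpoint dist 500),
      7 cis_kept (inward, dist 4700 > 1 kb), 8 outward_close (dist 4700),
      9 cis_kept (outward, dist 14500 > 5 kb), 10 cis_kept (same-strand,
      dist 500; no distance rule).
    """
    rows = [
        make_pair("chr1", 100, "+", "chr1", 50_000, "-", unique=False, rid="p1"),
        make_pair("chr1", 10_500, "+", "chr1", 50_500, "-", rid="p2"),
        make_pair("chr1", 10_500, "+", "chr1", 50_500, "+", rid="p3"),
        make_pair("chr1", 500, "+", "chr2", 300, "+", rid="p4"),
        make_pair("chr1", 42_000, "+", "chr1", 55_000, "-", rid="p5"),
        make_pair("chr1", 1_100, "+", "chr1", 1_700, "-", rid="p6"),
        make_pair("chr1", 1_100, "+", "chr1", 6_000, "-", rid="p7"),
        make_pair("chr1", 1_200, "-", "chr1", 6_100, "+", rid="p8"),
        make_pair("chr1", 500, "-", "chr1", 12_000, "+", rid="p9"),
        make_pair("chr1", 1_150, "+", "chr1", 1_750, "+", rid="p10"),
    ]
    expected = [
        "non_unique",
        "cis_kept",
        "positional_duplicate",
        "trans_kept",
        "same_fragment",
        "inward_close",
        "cis_kept",
        "outward_close",
        "cis_kept",
        "cis_kept",
    ]
    return pd.DataFrame(rows), expected


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)
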