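"""Spike-in normalization of ChIP-seq tag counts and peak intensities.

The sample with the fewest uniquely aligned spike-in tags is the reference;
every sample's factor is reference_count / sample_count, so the reference
factor is exactly 1 and all factors lie in (0, 1].  Peak intensities are
reported as RPKM (reads per kb per million primary-genome tags) scaled by the
sample's factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalization_factors", "normalize_peaks"]


def normalization_factors(counts: pd.DataFrame) -> dict[str, float]:
    """Per-sample spike-in scaling factors.

    ``counts`` carries columns ``sample`` and ``spikein_tags``.  Ties for the
    minimum count are resolved by sample-name order.  A zero spike-in count is
    an error naming the offending sample.
    """
    if len(counts) == 0:
        raise ValueError("empty spike-in count table")
    zero = counts.loc[counts["spikein_tags"] <= 0, "sample"]
    if len(zero):
        raise ValueError(f"zero spike-in tag count for sample {zero.iloc[0]!r}")
    ordered = counts.sort_values(["spikein_tags", "sample"], kind="mergesort")
    ref_count = float(ordered["spikein_tags"].iloc[0])
    return {
        str(row.sample): ref_count / float(row.spikein_tags)
        for row in counts.itertuples(index=False)
    }


def normalize_peaks(
    peaks: pd.DataFrame,
    factors: dict[str, float],
    primary_totals: dict[str, float],
) -> pd.DataFrame:
    """Spike-in-scaled RPKM per peak.

    ``peaks`` carries sample, peak identifier, raw tag ``count`` and peak
    ``length_bp``.  RPKM = count / (length_kb * total_primary/1e6), multiplied
    by the sample's spike-in factor.  Linear in raw counts and independent of
    row order.
    """
    out = peaks.copy()
    missing = set(out["sample"]) - set(factors)
    if missing:
        raise ValueError(f"no factor for samples: {sorted(missing)}")
    missing_tot = set(out["sample"]) - set(primary_totals)
    if missing_tot:
        raise ValueError(f"no primary tag total for samples: {sorted(missing_tot)}")
    if (out["length_bp"] <= 0).any():
        raise ValueError("peak lengths must be positive")
    length_kb = out["length_bp"].to_numpy(dtype=float) / 1000.0
    totals = out["sample"].map(primary_totals).to_numpy(dtype=float)
    f = out["sample"].map(factors).to_numpy(dtype=float)
    out["rpkm"] = out["count"].to_numpy(dtype=float) / (length_kb * totals / 1e6)
    out["normalized_rpkm"] = out["rpkm"] * f
    return out
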