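"""Integration of loop and compartment calls with expression data.

Covers DEG classification and summary percentages, loop-anchor-to-TSS
linkage, gene/loop association (Fisher exact), expression shifts in switched
compartments (rank-sum), relative qPCR quantification (2^-ddCt), and DEG-set
overlap enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loops import overlap_enrichment

__all__ = [
    "classify_degs",
    "deg_summary",
    "link_loops_to_genes",
    "loop_gene_association",
    "compartment_expression_shift",
    "ddct",
    "deg_overlap_enrichment",
]


def classify_degs(
    table: pd.DataFrame,
    p_thresh: float = 0.01,
    lfc_thresh: float = 1.0,
    extreme_lfc: float = 6.0,
) -> dict[str, set]:
    """Classify genes into up / down / extreme_up / extreme_down sets.

    up: p < p_thresh and log2fc > lfc_thresh (down symmetric).  Extreme sets
    additionally require |log2fc| >= extreme_lfc (inclusive; the 64-fold tier).
    """
    p = table["p"].to_numpy(dtype=float)
    lfc = table["log2fc"].to_numpy(dtype=float)
    genes = table["gene"].to_numpy()
    sig = p < p_thresh
    up = sig & (lfc > lfc_thresh)
    down = sig & (lfc < -lfc_thresh)
    return {
        "up": set(genes[up]),
        "down": set(genes[down]),
        "extreme_up": set(genes[up & (lfc >= extreme_lfc)]),
        "extreme_down": set(genes[down & (lfc <= -extreme_lfc)]),
    }


def _whole_percent(count: int, total: int) -> int:
    """Percentage rounded to the nearest whole percent, half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def deg_summary(total_expressed: int, sets: dict[str, set]) -> pd.DataFrame:
    """Counts and whole-percent fractions of each DEG set."""
    rows = []
    for name, members in sets.items():
        count = len(members)
        rows.append(
            {
                "set": name,
                "count": count,
                "fraction": count / total_expressed,
                "percent": _whole_percent(count, total_expressed),
            }
        )
    return pd.DataFrame(rows)


def link_loops_to_genes(
    loops: pd.DataFrame,
    tss_table: pd.DataFrame,
    resolution: int,
    window: int = 3000,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Pair loops with genes whose TSS lies within ``window`` of either anchor.

    Anchors are the half-open bin intervals [bin*res, (bin+1)*res); the
    distance from a TSS inside an anchor is 0, strand is ignored.  One row is
    emitted per (loop, gene) combination with the minimum anchor distance.
    """
    if len(loops) == 0 or len(tss_table) == 0:
        return pd.DataFrame(columns=["loop_id", "gene", "distance"])
    tss = tss_table["tss"].to_numpy(dtype=np.int64)
    genes = tss_table["gene"].to_numpy()
    if chrom is not None and "chrom" in tss_table.columns:
        sel = (tss_table["chrom"] == chrom).to_numpy()
        tss, genes = tss[sel], genes[sel]
    rows = []
    b1 = loops["bin1"].to_numpy(dtype=np.int64)
    b2 = loops["bin2"].to_numpy(dtype=np.int64)
    for loop_id in range(len(loops)):
        dmin = np.full(tss.shape, np.iinfo(np.int64).max, dtype=np.int64)
        for b in (b1[loop_id], b2[loop_id]):
            start, end = b * resolution, (b + 1) * resolution
            d = np.maximum.reduce([start - tss, tss - (end - 1), np.zeros_like(tss)])
            dmin = np.minimum(dmin, d)
        hit = dmin <= window
        for g, d in zip(genes[hit], dmin[hit]):
            rows.append({"loop_id": loop_id, "gene": g, "distance": int(d)})
    return pd.DataFrame(rows, columns=["loop_id", "gene", "distance"])


@dataclass
class AssociationResult:
    table: np.ndarray  # 2x2: rows gene up/down, cols adjacent loop gained/lost
    odds_ratio: float
    p: float
    unit: str  # 'combinations' or 'genes'


def loop_gene_association(
    diff_loops: pd.DataFrame,
    deg_sets: dict[str, set],
    linked_pairs: pd.DataFrame,
) -> dict[str, AssociationResult]:
    """2x2 association of gene regulation direction vs adjacent loop change.

    Because a gene may sit near several loops, two tallies are emitted: one
    over loop-gene combinations (every linked pair with a differential loop
    and a DEG counts once) and one over genes (genes adjacent to both gained
    and lost loops are excluded).  Fisher's exact test, two-sided.
    """
    status = diff_loops["status"].to_numpy()
    results: dict[str, AssociationResult] = {}
    if len(linked_pairs) == 0:
        empty = np.zeros((2, 2), dtype=int)
        return {
            "combinations": AssociationResult(empty, np.nan, 1.0, "combinations"),
            "genes": AssociationResult(empty.copy(), np.nan, 1.0, "genes"),
        }

    lp = linked_pairs.copy()
    lp["loop_status"] = status[lp["loop_id"].to_numpy()]
    lp = lp[lp["loop_status"].isin(["gained", "lost"])]
    lp["gene_dir"] = np.where(
        lp["gene"].isin(deg_sets["up"]),
        "up",
        np.where(lp["gene"].isin(deg_sets["down"]), "down", "none"),
    )
    lp = lp[lp["gene_dir"] != "none"]

    def _fisher(tab: np.ndarray) -> tuple[float, float]:
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        return float(odds), float(p)

    # combinations tally
    tab = np.zeros((2, 2), dtype=int)
    for i, gd in enumerate(("up", "down")):
        for j, ls in enumerate(("gained", "lost")):
            tab[i, j] = int(((lp["gene_dir"] == gd) & (lp["loop_status"] == ls)).sum())
    odds, p = _fisher(tab)
    results["combinations"] = AssociationResult(tab, odds, p, "combinations")

    # gene-level tally: each gene once; drop genes adjacent to both directions
    per_gene = lp.groupby("gene").agg(
        gene_dir=("gene_dir", "first"),
        n_status=("loop_status", "nunique"),
        loop_status=("loop_status", "first"),
    )
    per_gene = per_gene[per_gene["n_status"] == 1]
    tab_g = np.zeros((2, 2), dtype=int)
    for i, gd in enumerate(("up", "down")):
        for j, ls in enumerate(("gained", "lost")):
            tab_g[i, j] = int(
                ((per_gene["gene_dir"] == gd) & (per_gene["loop_status"] == ls)).sum()
            )
    odds_g, p_g = _fisher(tab_g)
    results["genes"] = AssociationResult(tab_g, odds_g, p_g, "genes")
    return results


def compartment_expression_shift(
    switches: pd.DataFrame,
    de_table: pd.DataFrame,
    resolution: int = 250_000,
) -> dict[str, dict]:
    """Expression log2FC distributions per switch class, tested against stable.

    Genes are assigned to the switch class of the bin containing their TSS.
    Each switched class is compared with the stable class by a two-sided
    rank-sum test; an empty class is reported with ``n == 0`` and no p-value
    rather than raising.
    """
    bins = (de_table["tss"].to_numpy(dtype=np.int64)) // resolution
    klass_by_bin = switches.set_index("bin")["switch_class"]
    gene_class = klass_by_bin.reindex(bins).fillna("masked").to_numpy()
    lfc = de_table["log2fc"].to_numpy(dtype=float)

    out: dict[str, dict] = {}
    stable = lfc[gene_class == "stable"]
    for klass in ("A_to_B", "B_to_A", "stable"):
        vals = lfc[gene_class == klass]
        entry = {
            "n": int(vals.size),
            "median_log2fc": float(np.median(vals)) if vals.size else None,
            "p_vs_stable": None,
        }
        if klass != "stable" and vals.size and stable.size:
            res = stats.mannwhitneyu(
                vals, stable, alternative="two-sided", method="asymptotic"
            )
            entry["p_vs_stable"] = float(res.pvalue)
        out[klass] = entry
    return out


def ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    reference_sample: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is a long table (sample, gene, ct).  dCt = Ct_target - Ct_reference
    gene within each sample; ddCt subtracts the reference sample's dCt; the
    relative expression is 2^-ddCt (exactly 1 for the reference sample).
    """
    wide = ct.pivot(index="sample", columns="gene", values="ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    if reference_sample not in wide.index:
        raise ValueError(f"reference sample {reference_sample!r} missing from Ct table")
    if wide.isna().any().any():
        raise ValueError("Ct table has missing sample x gene entries")
    dct = wide.sub(wide[reference_gene], axis=0)
    ddct_vals = dct.sub(dct.loc[reference_sample], axis=1)
    rel = np.power(2.0, -ddct_vals)
    out = rel.drop(columns=[reference_gene]).reset_index().melt(
        id_vars="sample", var_name="gene", value_name="relative_expression"
    )
    return out.sort_values(["sample", "gene"]).reset_index(drop=True)


def deg_overlap_enrichment(
    set_a,
    set_b,
    universe_a,
    universe_b,
) -> tuple[int, float, float, float]:
    """Fold over chance and hypergeometric p for two DEG sets.

    The universe is the intersection of the two expressed-gene universes;
    both sets are restricted to it before testing.
    """
    universe = set(universe_a) & set(universe_b)
    sa = set(set_a) & universe
    sb = set(set_b) & universe
    return overlap_enrichment(sa, sb, len(universe))
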