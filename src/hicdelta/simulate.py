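"""Synthetic paired-condition Hi-C data with planted, recoverable structure.

One generator produces everything the downstream analysis consumes: a pair of
condition contact matrices sharing a backbone (power-law distance decay,
compartment checkerboard, TAD blocks) but differing in planted condition-
specific loops and compartment switches; raw read-pair streams with labelled
filter artifacts; expression count tables coupled to the planted loops and
switches; and spike-in tag counts.  A :class:`TruthRecord` captures every
planted structure so recovery can be asserted exactly.

Randomness: one master seed; independent substreams are derived with
``numpy.random.SeedSequence.spawn`` in a fixed order (structure, noise A,
noise B), so a given config reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "SimConfig",
    "PlantedLoop",
    "TruthRecord",
    "simulate_condition_pair",
    "simulate_read_pairs",
    "simulate_expression",
    "de_table_from_counts",
    "simulate_spikein",
    "random_digest_cuts",
]

COMPARTMENT_BIN = 250_000


@dataclass
class SimConfig:
    chrom: str = "chrS"
    chrom_length: int = 20_000_000
    resolution: int = 5_000
    compartment_block_size: int = 1_000_000
    tad_size: int = 2_000_000
    decay_exponent: float = 1.0
    compartment_strength: float = 0.0  # alpha in [0, 1)
    tad_boost: float = 1.0
    loop_boost: float = 4.0
    n_loops_common: int = 0
    n_loops_condA_only: int = 0
    n_loops_condB_only: int = 0
    loop_size_median_A: int = 700_000
    loop_size_median_B: int = 200_000
    loop_size_median_common: int = 300_000
    loop_size_sigma: float = 0.25
    n_switch_A_to_B: int = 0
    n_switch_B_to_A: int = 0
    sequencing_depth: float = 2_000_000.0
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length % self.resolution != 0:
            raise ValueError("resolution must divide chrom_length")
        if self.compartment_block_size % self.resolution != 0:
            raise ValueError("resolution must divide compartment_block_size")
        if self.compartment_block_size % COMPARTMENT_BIN != 0:
            raise ValueError(
                f"compartment_block_size must be a multiple of {COMPARTMENT_BIN}"
            )
        if self.chrom_length % self.compartment_block_size != 0:
            raise ValueError("compartment_block_size must divide chrom_length")
        if self.tad_size % self.resolution != 0:
            raise ValueError("resolution must divide tad_size")
        if not (0 <= self.compartment_strength < 1):
            raise ValueError("compartment_strength must be in [0, 1)")
        for name in ("tad_boost", "loop_boost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "loop_size_median_A",
            "loop_size_median_B",
            "loop_size_median_common",
        ):
            v = getattr(self, name)
            if not (2 * self.resolution <= v < self.chrom_length):
                raise ValueError(
                    f"{name}={v} must lie in [2*resolution, chrom_length)"
                )
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.resolution


@dataclass
class PlantedLoop:
    anchor1_bin: int
    anchor2_bin: int
    condition: str  # common | A_only | B_only
    boost: float
    size_bp: int


@dataclass
class TruthRecord:
    """Ground truth of one simulated condition pair."""

    labels_a: np.ndarray  # 'A'/'B' per 250 kb bin, condition A
    labels_b: np.ndarray
    switched_bins: list[int]
    tad_boundaries: list[int]  # bin indices at matrix resolution
    loops: list[PlantedLoop]
    de_genes: pd.DataFrame | None = None
    config: SimConfig | None = None

    def validate(self) -> None:
        sym_diff = [int(i) for i in np.nonzero(self.labels_a != self.labels_b)[0]]
        if sorted(self.switched_bins) != sym_diff:
            raise AssertionError("switched_bins != symmetric difference of labels")
        for lp in self.loops:
            if lp.condition not in ("common", "A_only", "B_only"):
                raise AssertionError(f"bad loop condition {lp.condition}")

    def loops_for(self, condition: str) -> list[PlantedLoop]:
        key = {"A": "A_only", "B": "B_only"}[condition]
        return [lp for lp in self.loops if lp.condition in ("common", key)]

    def to_dict(self) -> dict:
        return {
            "labels_a": self.labels_a.tolist(),
            "labels_b": self.labels_b.tolist(),
            "switched_bins": list(map(int, self.switched_bins)),
            "tad_boundaries": list(map(int, self.tad_boundaries)),
            "loops": [asdict(lp) for lp in self.loops],
            "config": asdict(self.config) if self.config else None,
        }


def _plant_loops(cfg: SimConfig, rng: np.random.Generator) -> list[PlantedLoop]:
    n = cfg.n_bins
    res = cfg.resolution
    specs = [
        ("common", cfg.n_loops_common, cfg.loop_size_median_common),
        ("A_only", cfg.n_loops_condA_only, cfg.loop_size_median_A),
        ("B_only", cfg.n_loops_condB_only, cfg.loop_size_median_B),
    ]
    used: set[tuple[int, int]] = set()
    loops: list[PlantedLoop] = []
    for condition, count, median in specs:
        for _ in range(count):
            for _attempt in range(1000):
                size = float(
                    np.exp(rng.normal(math.log(median), cfg.loop_size_sigma))
                )
                sep = max(2, int(round(size / res)))
                if sep >= n - 1:
                    continue
                a1 = int(rng.integers(0, n - sep))
                a2 = a1 + sep
                # keep planted pixels well separated so scoring windows
                # never see a neighbouring planted peak in their background
                if any(
                    abs(a1 - u1) <= 3 and abs(a2 - u2) <= 3 for u1, u2 in used
                ):
                    continue
                used.add((a1, a2))
                loops.append(
                    PlantedLoop(a1, a2, condition, cfg.loop_boost, sep * res)
                )
                break
            else:
                raise ValueError(
                    "could not place a loop; anchor distance exceeds chromosome "
                    "or the grid is saturated"
                )
    return loops


def _compartment_vectors(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block spin (+1 = A, -1 = B) for each condition."""
    nb = cfg.chrom_length // cfg.compartment_block_size
    spins_a = rng.choice([1.0, -1.0], size=nb)
    # guarantee enough blocks of each label to host the requested switches
    if (spins_a == 1).sum() < cfg.n_switch_A_to_B or (
        spins_a == -1
    ).sum() < cfg.n_switch_B_to_A:
        raise ValueError("not enough blocks of the required label to plant switches")
    spins_b = spins_a.copy()
    a_blocks = np.flatnonzero(spins_a == 1)
    b_blocks = np.flatnonzero(spins_a == -1)
    flip_a = rng.choice(a_blocks, size=cfg.n_switch_A_to_B, replace=False)
    flip_b = rng.choice(b_blocks, size=cfg.n_switch_B_to_A, replace=False)
    spins_b[flip_a] = -1.0
    spins_b[flip_b] = 1.0
    return spins_a, spins_b


def _expected_matrix(
    cfg: SimConfig, spins: np.ndarray, loops: list[PlantedLoop], condition: str
) -> np.ndarray:
    n = cfg.n_bins
    res = cfg.resolution
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    # the decay law takes only n distinct values; build it once per diagonal
    decay = np.zeros(n)
    decay[1:] = (np.arange(1, n, dtype=np.float64) * res) ** (-cfg.decay_exponent)
    E = decay[d]
    # compartment checkerboard
    per_block = cfg.compartment_block_size // res
    c = np.repeat(spins, per_block)
    E *= 1.0 + cfg.compartment_strength * np.outer(c, c)
    # TAD blocks
    if cfg.tad_boost != 1.0:
        tad_id = (idx * res) // cfg.tad_size
        same_tad = tad_id[:, None] == tad_id[None, :]
        E[same_tad] *= cfg.tad_boost
    # focal loops: single-pixel boost plus a one-pixel shoulder at half boost
    key = {"A": "A_only", "B": "B_only"}[condition]
    shoulder = 1.0 + (cfg.loop_boost - 1.0) / 2.0
    for lp in loops:
        if lp.condition not in ("common", key):
            continue
        i, j = lp.anchor1_bin, lp.anchor2_bin
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ii, jj = i + di, j + dj
                if 0 <= ii < n and 0 <= jj < n and ii < jj:
                    f = lp.boost if (di == 0 and dj == 0) else shoulder
                    E[ii, jj] *= f
                    E[jj, ii] *= f
    np.fill_diagonal(E, 0.0)
    total = np.triu(E, 1).sum()
    E *= cfg.sequencing_depth / total
    return E


def expected_condition_pair(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Noiseless expected matrices (and truth) for a config."""
    ss = np.random.SeedSequence(cfg.seed)
    structure_rng = np.random.default_rng(ss.spawn(3)[0])
    spins_a, spins_b = _compartment_vectors(cfg, structure_rng)
    loops = _plant_loops(cfg, structure_rng)
    EA = _expected_matrix(cfg, spins_a, loops, "A")
    EB = _expected_matrix(cfg, spins_b, loops, "B")
    truth = _build_truth(cfg, spins_a, spins_b, loops)
    return EA, EB, truth


def _build_truth(cfg, spins_a, spins_b, loops) -> TruthRecord:
    per_block_250k = cfg.compartment_block_size // COMPARTMENT_BIN
    labels_a = np.where(np.repeat(spins_a, per_block_250k) > 0, "A", "B")
    labels_b = np.where(np.repeat(spins_b, per_block_250k) > 0, "A", "B")
    switched = [int(i) for i in np.nonzero(labels_a != labels_b)[0]]
    n_tads = cfg.chrom_length // cfg.tad_size
    tad_boundaries = [
        int(k * cfg.tad_size // cfg.resolution) for k in range(1, n_tads)
    ]
    truth = TruthRecord(
        labels_a=labels_a,
        labels_b=labels_b,
        switched_bins=switched,
        tad_boundaries=tad_boundaries,
        loops=loops,
        config=cfg,
    )
    truth.validate()
    return truth


def simulate_condition_pair(
    cfg: SimConfig,
) -> tuple[ContactMatrix, ContactMatrix, TruthRecord]:
    """Simulate a pair of condition contact matrices plus ground truth.

    Counts are drawn independently per upper-triangle pixel from a Poisson
    law whose mean is the depth-scaled product of distance decay, compartment
    checkerboard, TAD, and loop factors; the matrix is then mirrored so it is
    exactly symmetric.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seqs = ss.spawn(3)
    structure_rng = np.random.default_rng(seqs[0])
    spins_a, spins_b = _compartment_vectors(cfg, structure_rng)
    loops = _plant_loops(cfg, structure_rng)
    truth = _build_truth(cfg, spins_a, spins_b, loops)

    mats = []
    for spins, condition, seq in (
        (spins_a, "A", seqs[1]),
        (spins_b, "B", seqs[2]),
    ):
        E = _expected_matrix(cfg, spins, loops, condition)
        rng = np.random.default_rng(seq)
        counts = np.triu(rng.poisson(E).astype(np.float64), 1)
        counts += counts.T
        mats.append(
            ContactMatrix(
                chrom=cfg.chrom,
                chrom_length=cfg.chrom_length,
                resolution=cfg.resolution,
                counts=counts,
            )
        )
    return mats[0], mats[1], truth


# ---------------------------------------------------------------------------
# read-pair stream with labelled artifacts


def random_digest_cuts(
    chrom_length: int, mean_spacing: int, seed: int | None = None
) -> np.ndarray:
    """Random cut positions with roughly geometric spacing (motif-like)."""
    rng = np.random.default_rng(seed)
    n = int(2 * chrom_length / mean_spacing)
    gaps = rng.geometric(1.0 / mean_spacing, size=n)
    pos = np.cumsum(gaps)
    return pos[pos < chrom_length].astype(np.int64)


ARTIFACT_CLASSES = (
    "non_unique",
    "positional_duplicate",
    "same_fragment",
    "inward_close",
    "outward_close",
    "trans_kept",
)


def simulate_read_pairs(
    n: int,
    digest,
    artifact_rates: dict[str, float] | None = None,
    seed: int | None = None,
    inward_max: int = 1000,
    outward_max: int = 5000,
) -> pd.DataFrame:
    """Simulate a read-pair table with planted, labelled filter artifacts.

    ``artifact_rates`` maps artifact class names (see ``ARTIFACT_CLASSES``)
    to fractions of the stream; remaining pairs are clean cis pairs whose
    fragment midpoints are more than ``outward_max`` apart, so they survive
    every distance rule regardless of orientation.  The returned frame
    carries a ``truth_label`` column naming the disposition the filter must
    assign to each record.
    """
    from .pairs import DigestIndex  # local import to avoid cycle at module load

    artifact_rates = dict(artifact_rates or {})
    unknown = set(artifact_rates) - set(ARTIFACT_CLASSES)
    if unknown:
        raise ValueError(f"unknown artifact classes: {sorted(unknown)}")
    if any(v < 0 for v in artifact_rates.values()):
        raise ValueError("artifact rates must be non-negative")
    if sum(artifact_rates.values()) > 1:
        raise ValueError("artifact rates sum above 1")
    rng = np.random.default_rng(seed)

    chroms = sorted(digest.boundaries)
    main = chroms[0]
    mids = digest.midpoints(main)
    bnd = digest.boundaries[main]
    nfrag = len(mids)
    if artifact_rates.get("trans_kept", 0) > 0 and len(chroms) < 2:
        raise ValueError("trans pairs requested but digest has a single chromosome")

    # fragment pairs by midpoint distance class
    order = np.arange(nfrag)

    def _sample_pos(frag: int) -> int:
        lo, hi = bnd[frag], bnd[frag + 1]
        return int(rng.integers(lo, hi))

    def _pair_with_min_distance(min_dist: float) -> tuple[int, int]:
        for _ in range(10000):
            f1 = int(rng.integers(0, nfrag))
            f2 = int(rng.integers(0, nfrag))
            if f1 == f2:
                continue
            if f1 > f2:
                f1, f2 = f2, f1
            if mids[f2] - mids[f1] > min_dist:
                return f1, f2
        raise RuntimeError("digest too small to sample distant fragment pairs")

    def _pair_with_distance_in(lo: float, hi: float) -> tuple[int, int]:
        # scan from a random start for an adjacent-ish pair in the band
        for _ in range(10000):
            f1 = int(rng.integers(0, nfrag - 1))
            for f2 in range(f1 + 1, min(f1 + 50, nfrag)):
                d = mids[f2] - mids[f1]
                if lo < d <= hi:
                    return f1, f2
                if d > hi:
                    break
        raise RuntimeError(
            f"digest has no fragment pairs with midpoint distance in ({lo}, {hi}]"
        )

    counts = {k: int(round(artifact_rates.get(k, 0.0) * n)) for k in ARTIFACT_CLASSES}
    n_clean = n - sum(counts.values())
    if n_clean < 0:
        raise ValueError("artifact counts exceed n")

    rows = []
    used_keys: set[tuple] = set()

    def _emit(chrom1, pos1, s1, chrom2, pos2, s2, unique, label):
        rows.append(
            {
                "readID": f"r{len(rows)}",
                "chrom1": chrom1,
                "pos1": pos1,
                "chrom2": chrom2,
                "pos2": pos2,
                "strand1": s1,
                "strand2": s2,
                "unique": unique,
                "truth_label": label,
            }
        )

    clean_rows = []
    for _ in range(n_clean):
        for _attempt in range(10000):
            f1, f2 = _pair_with_min_distance(outward_max)
            p1, p2 = _sample_pos(f1), _sample_pos(f2)
            key = (main, p1, main, p2)
            if key not in used_keys:
                used_keys.add(key)
                break
        s1, s2 = rng.choice(["+", "-"]), rng.choice(["+", "-"])
        clean_rows.append((main, p1, s1, main, p2, s2))
        _emit(main, p1, s1, main, p2, s2, True, "cis_kept")

    for _ in range(counts["positional_duplicate"]):
        if not clean_rows:
            raise ValueError("cannot plant duplicates without clean pairs")
        src = clean_rows[int(rng.integers(0, len(clean_rows)))]
        _emit(src[0], src[1], rng.choice(["+", "-"]), src[3], src[4],
              rng.choice(["+", "-"]), True, "positional_duplicate")

    for _ in range(counts["non_unique"]):
        f1, f2 = _pair_with_min_distance(outward_max)
        _emit(main, _sample_pos(f1), rng.choice(["+", "-"]), main,
              _sample_pos(f2), rng.choice(["+", "-"]), False, "non_unique")

    def _fresh(p1, p2):
        key = (main, p1, main, p2)
        if key in used_keys:
            return False
        used_keys.add(key)
        return True

    for _ in range(counts["same_fragment"]):
        for _attempt in range(10000):
            f = int(rng.integers(0, nfrag))
            if bnd[f + 1] - bnd[f] < 2:
                continue
            p1, p2 = sorted(
                (
                    int(rng.integers(bnd[f], bnd[f + 1])),
                    int(rng.integers(bnd[f], bnd[f + 1])),
                )
            )
            if _fresh(p1, p2):
                break
        _emit(main, p1, rng.choice(["+", "-"]), main, p2,
              rng.choice(["+", "-"]), True, "same_fragment")

    for _ in range(counts["inward_close"]):
        for _attempt in range(10000):
            f1, f2 = _pair_with_distance_in(0, inward_max)
            p1, p2 = _sample_pos(f1), _sample_pos(f2)
            if _fresh(p1, p2):
                break
        _emit(main, p1, "+", main, p2, "-", True, "inward_close")

    for _ in range(counts["outward_close"]):
        for _attempt in range(10000):
            f1, f2 = _pair_with_distance_in(0, outward_max)
            p1, p2 = _sample_pos(f1), _sample_pos(f2)
            if _fresh(p1, p2):
                break
        _emit(main, p1, "-", main, p2, "+", True, "outward_close")

    for _ in range(counts["trans_kept"]):
        other = chroms[1]
        p1 = int(rng.integers(0, digest.chrom_length(main)))
        p2 = int(rng.integers(0, digest.chrom_length(other)))
        _emit(main, p1, rng.choice(["+", "-"]), other, p2,
              rng.choice(["+", "-"]), True, "trans_kept")

    # record order matters: positional duplicates must follow their source pair
    # (de-duplication keeps the first occurrence), so the stream is not shuffled.
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression coupled to planted structure


def simulate_expression(
    truth: TruthRecord,
    n_genes: int,
    seed: int | None = None,
    baseline_mean: float = 200.0,
    dispersion: float = 0.05,
    lfc_loop: float = 2.0,
    lfc_switch: float = 1.0,
    n_reps: int = 3,
    window: int = 3000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate expression counts coupled to planted loops and switches.

    Genes receive uniform TSS positions.  A gene whose TSS lies within
    ``window`` bp of an anchor of a condition-specific loop gets the loop
    fold-change (higher in the condition carrying the loop); a gene inside a
    switched 250 kb bin gets the switch fold-change (B->A switched bins are
    up in condition B).  Log2 fold-changes are reported as condition B over
    condition A.  Counts are negative-binomial around the per-condition mean.
    """
    cfg = truth.config
    if cfg is None:
        raise ValueError("truth record carries no config")
    rng = np.random.default_rng(seed)
    res = cfg.resolution
    tss = rng.integers(0, cfg.chrom_length, size=n_genes)
    tss.sort()
    true_lfc = np.zeros(n_genes)
    reason = np.array(["none"] * n_genes, dtype=object)

    for lp in truth.loops:
        if lp.condition == "common":
            continue
        sign = -1.0 if lp.condition == "A_only" else 1.0
        for anchor in (lp.anchor1_bin, lp.anchor2_bin):
            lo, hi = anchor * res - window, (anchor + 1) * res + window
            sel = (tss >= lo) & (tss < hi)
            true_lfc[sel] = sign * lfc_loop
            reason[sel] = lp.condition + "_loop"

    switch_bin = tss // COMPARTMENT_BIN
    for b in truth.switched_bins:
        sel = switch_bin == b
        sign = 1.0 if truth.labels_b[b] == "A" else -1.0  # B->A switched up in B
        # loop-coupling takes precedence over compartment coupling
        free = sel & (reason == "none")
        true_lfc[free] = sign * lfc_switch
        reason[free] = ("B_to_A" if sign > 0 else "A_to_B") + "_switch"

    mu_a = np.full(n_genes, baseline_mean)
    mu_b = baseline_mean * np.power(2.0, true_lfc)

    def _nb(mu):
        if dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    data = {"gene": [f"g{i:05d}" for i in range(n_genes)]}
    for rep in range(n_reps):
        data[f"condA_rep{rep + 1}"] = _nb(mu_a)
    for rep in range(n_reps):
        data[f"condB_rep{rep + 1}"] = _nb(mu_b)
    counts = pd.DataFrame(data)
    de_truth = pd.DataFrame(
        {
            "gene": counts["gene"],
            "chrom": cfg.chrom,
            "tss": tss,
            "strand": "+",
            "true_log2fc": true_lfc,
            "reason": reason,
        }
    )
    return counts, de_truth


def de_table_from_counts(
    counts: pd.DataFrame, de_truth: pd.DataFrame
) -> pd.DataFrame:
    """Summarize simulated counts into a DE table (log2FC of B over A, Welch t
    on log2 counts)."""
    from scipy import stats

    a_cols = [c for c in counts.columns if c.startswith("condA")]
    b_cols = [c for c in counts.columns if c.startswith("condB")]
    a = counts[a_cols].to_numpy(dtype=float)
    b = counts[b_cols].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "gene": counts["gene"],
            "chrom": de_truth["chrom"],
            "tss": de_truth["tss"],
            "strand": de_truth["strand"],
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# spike-in counts


def simulate_spikein(
    sample_means: dict[str, tuple[float, float]],
    cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate (primary, spike-in) tag counts per sample.

    Counts are drawn from a normal law around the configured means with
    coefficient of variation ``cv`` and clipped at 1; ``cv=0`` reproduces the
    configured means exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample, (human_mean, spike_mean) in sample_means.items():
        if cv > 0:
            h = max(1, int(round(rng.normal(human_mean, cv * human_mean))))
            s = max(1, int(round(rng.normal(spike_mean, cv * spike_mean))))
        else:
            h, s = int(round(human_mean)), int(round(spike_mean))
        rows.append({"sample": sample, "primary_tags": h, "spikein_tags": s})
    return pd.DataFrame(rows)
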