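"""Contact matrices: construction, balancing, expected models, loop scoring,
and insulation profiling.

A :class:`ContactMatrix` holds a symmetric dense count matrix for a single
chromosome at a fixed resolution, together with an optional per-bin validity
mask and balancing weights.  Dense storage is deliberate: the pipeline targets
single-chromosome, desk-scale maps (up to a few thousand bins) where dense
linear algebra and convolution are both simpler and faster than sparse paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ContactMatrix",
    "LoopScoreMap",
    "build_matrix",
    "balance",
    "expected_by_distance",
    "loop_score",
    "insulation_profile",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    Parameters
    ----------
    chrom : chromosome name.
    chrom_length : chromosome length in bp.
    resolution : bin size in bp.
    counts : (n, n) symmetric non-negative array.
    weights : per-bin balancing weights, or None if unbalanced.  Masked bins
        carry weight 0.
    mask : boolean array, True for retained (analyzable) bins.
    converged : set by :func:`balance`; None when never balanced.
    """

    chrom: str
    chrom_length: int
    resolution: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    mask: np.ndarray | None = None
    converged: bool | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {n}) expected from "
                f"chrom_length={self.chrom_length}, resolution={self.resolution}"
            )
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts matrix is not symmetric")
        if self.counts.min(initial=0.0) < 0:
            raise ValueError("counts matrix has negative entries")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.resolution)

    def balanced(self) -> np.ndarray:
        """Balanced matrix (weights applied); masked rows/columns are zero."""
        if self.weights is None:
            out = self.counts.copy()
        else:
            w = np.where(self.mask, self.weights, 0.0)
            out = self.counts * np.outer(w, w)
        out[~self.mask, :] = 0.0
        out[:, ~self.mask] = 0.0
        return out

    def coarsen(self, factor: int) -> "ContactMatrix":
        """Aggregate counts into ``factor``-times-larger bins."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        n = self.n_bins
        n_coarse = -(-n // factor)
        pad = n_coarse * factor - n
        c = self.counts
        if pad:
            c = np.pad(c, ((0, pad), (0, pad)))
        c = c.reshape(n_coarse, factor, n_coarse, factor).sum(axis=(1, 3))
        return ContactMatrix(
            chrom=self.chrom,
            chrom_length=self.chrom_length,
            resolution=self.resolution * factor,
            counts=c,
        )

    def to_triplets(self) -> pd.DataFrame:
        """Upper-triangle sparse representation in bp start coordinates."""
        iu, ju = np.nonzero(np.triu(self.counts))
        return pd.DataFrame(
            {
                "bin1_start": iu * self.resolution,
                "bin2_start": ju * self.resolution,
                "count": self.counts[iu, ju],
            }
        )


def build_matrix(
    anchor_counts: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    resolution: int,
) -> ContactMatrix:
    """Build a symmetric matrix from an anchor-pair count table.

    ``anchor_counts`` carries integer bin indices ``bin1``/``bin2`` and a
    ``count`` column, as produced by :func:`hicdelta.pairs.bin_to_anchors`.
    """
    n = -(-chrom_length // resolution)
    counts = np.zeros((n, n), dtype=np.float64)
    if len(anchor_counts):
        b1 = anchor_counts["bin1"].to_numpy(dtype=np.int64)
        b2 = anchor_counts["bin2"].to_numpy(dtype=np.int64)
        c = anchor_counts["count"].to_numpy(dtype=np.float64)
        if (b1 < 0).any() or (b2 < 0).any() or (b1 >= n).any() or (b2 >= n).any():
            raise ValueError("anchor bin beyond chromosome end")
        np.add.at(counts, (b1, b2), c)
        np.add.at(counts, (b2, b1), c)
        # diagonal got added twice
        diag_mask = b1 == b2
        if diag_mask.any():
            np.add.at(counts, (b1[diag_mask], b1[diag_mask]), -c[diag_mask])
    return ContactMatrix(chrom=chrom, chrom_length=chrom_length, resolution=resolution, counts=counts)


def balance(
    m: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 500,
    mask_low_coverage_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative proportional fitting (matrix balancing).

    Bins with zero coverage, and bins whose coverage falls strictly below the
    ``mask_low_coverage_frac`` quantile of nonzero coverages, are masked out.
    Iterates until the coefficient of variation of unmasked row sums drops
    below ``tol``; non-convergence is flagged (``converged=False``) and warned
    about, never silent.  Weights are scaled so the balanced matrix preserves
    the total unmasked raw count.
    """
    A = m.counts
    n = A.shape[0]
    cov = A.sum(axis=1)
    mask = cov > 0
    if mask.any() and mask_low_coverage_frac > 0:
        thr = np.quantile(cov[mask], mask_low_coverage_frac)
        mask &= cov >= thr
    b = np.zeros(n)
    b[mask] = 1.0
    converged = False
    if mask.sum() == 0:
        warnings.warn("balance: no unmasked bins; returning zero weights")
        return replace(m, weights=b, mask=mask, converged=False)
    for _ in range(max_iter):
        s = b * (A @ b)
        sm = s[mask]
        mean = sm.mean()
        if mean <= 0:
            break
        cv = sm.std() / mean
        if cv < tol:
            converged = True
            break
        b[mask] /= np.sqrt(sm / mean)
    if not converged:
        warnings.warn(f"balance: did not converge in {max_iter} iterations (cv={cv:.3g})")
    # preserve total unmasked count
    sub = np.outer(mask, mask)
    raw_total = A[sub].sum()
    bal_total = (A * np.outer(b, b))[sub].sum()
    if bal_total > 0:
        b *= np.sqrt(raw_total / bal_total)
    return replace(m, weights=b, mask=mask, converged=converged)


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean balanced count per bin-separation over unmasked pixels.

    Entry ``d`` is the mean over all pixels ``(i, i+d)`` with both bins
    unmasked; NaN where no such pixel exists.
    """
    B = m.balanced()
    mask = m.mask
    n = B.shape[0]
    out = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(B, offset=d)
        vm = mask[: n - d] & mask[d:]
        if vm.any():
            out[d] = diag[vm].mean()
    return out


@dataclass
class LoopScoreMap:
    """Per-pixel loop-strength scores: balanced count over local background."""

    pixels: pd.DataFrame  # bin1, bin2, balanced, expected, background, score
    resolution: int
    n_skipped: int = 0
    chrom: str = ""

    def sizes(self) -> np.ndarray:
        """Genomic size (bp) of every scored anchor pair."""
        return (
            (self.pixels["bin2"] - self.pixels["bin1"]).to_numpy() * self.resolution
        )


def loop_score(
    m: ContactMatrix,
    expected: np.ndarray | None = None,
    window: int = 5,
    min_separation: int = 2,
    max_separation_bp: int = 2_000_000,
    floor_frac: float = 0.05,
) -> LoopScoreMap:
    """Score every eligible pixel by enrichment over its local background.

    Background at (i, j) is the mean balanced count in the (2w+1)^2 square
    centred there, excluding the central 3x3 (so a focal peak cannot inflate
    its own background) and masked bins.  The score divides the balanced count
    by max(background, floor) where floor = ``floor_frac`` x expected count at
    that separation, avoiding blow-up where the background is nearly empty.
    Pixels whose window would cross the matrix edge are skipped and counted in
    ``n_skipped``.
    """
    if expected is None:
        expected = expected_by_distance(m)
    B = m.balanced()
    mask = m.mask
    n = B.shape[0]
    w = window
    V = np.outer(mask, mask).astype(np.float64)

    def _boxsum(x, k):
        return ndimage.uniform_filter(x, size=k, mode="constant") * (k * k)

    big_sum = _boxsum(B, 2 * w + 1)
    big_cnt = _boxsum(V, 2 * w + 1)
    in_sum = _boxsum(B, 3)
    in_cnt = _boxsum(V, 3)
    bg_sum = big_sum - in_sum
    bg_cnt = np.maximum(np.rint(big_cnt - in_cnt), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bg = np.where(bg_cnt > 0, bg_sum / np.maximum(bg_cnt, 1), np.nan)

    max_sep = min(n - 1, max_separation_bp // m.resolution)
    rows = {k: [] for k in ("bin1", "bin2", "balanced", "expected", "background", "score")}
    n_skipped = 0
    for d in range(min_separation, max_sep + 1):
        i = np.arange(n - d)
        j = i + d
        valid = mask[i] & mask[j]
        in_bounds = (i >= w) & (j < n - w)
        n_skipped += int((valid & ~in_bounds).sum())
        sel = valid & in_bounds
        if not sel.any():
            continue
        ii, jj = i[sel], j[sel]
        bgv = bg[ii, jj]
        exp_d = expected[d]
        floor = floor_frac * exp_d if np.isfinite(exp_d) else 0.0
        ok = np.isfinite(bgv) & (bgv > 0)
        ii, jj, bgv = ii[ok], jj[ok], bgv[ok]
        if ii.size == 0:
            continue
        denom = np.maximum(bgv, floor)
        bal = B[ii, jj]
        rows["bin1"].append(ii)
        rows["bin2"].append(jj)
        rows["balanced"].append(bal)
        rows["expected"].append(np.full(ii.size, exp_d))
        rows["background"].append(bgv)
        rows["score"].append(bal / denom)
    if rows["bin1"]:
        df = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    else:
        df = pd.DataFrame({k: np.array([]) for k in rows})
    return LoopScoreMap(pixels=df, resolution=m.resolution, n_skipped=n_skipped, chrom=m.chrom)


def insulation_profile(
    m: ContactMatrix,
    window: int = 10,
    delta: float = 0.5,
) -> tuple[np.ndarray, list[int]]:
    """Insulation score per bin and boundary calls.

    The score at bin ``i`` is log2 of the mean balanced count in the
    ``window x window`` square crossing the bin (rows ``[i-w, i)``, columns
    ``[i, i+w)``) divided by the chromosome-wide mean of that statistic.
    With this square, a sharp block junction between bins ``i-1`` and ``i``
    has a unique fully-crossing minimum at ``i``, so boundary positions are
    stable under noise.  Boundaries are local minima within +-w whose score
    is <= -``delta``; runs of tied minima are merged and reported at the run
    midpoint (rounded up).
    """
    B = m.balanced()
    mask = m.mask
    n = B.shape[0]
    w = window
    means = np.full(n, np.nan)
    V = np.outer(mask, mask)
    for i in range(w, n - w):
        sub = B[i - w : i, i : i + w]
        vm = V[i - w : i, i : i + w]
        if vm.any():
            means[i] = sub[vm].mean()
    global_mean = np.nanmean(means)
    if not np.isfinite(global_mean) or global_mean <= 0:
        return np.full(n, np.nan), []
    with np.errstate(divide="ignore"):
        scores = np.log2(np.maximum(means, 1e-300) / global_mean)
        scores[np.isnan(means)] = np.nan

    candidates = []
    for i in range(w, n - w):
        s = scores[i]
        if np.isnan(s):
            continue
        lo, hi = max(0, i - w), min(n, i + w + 1)
        neigh = scores[lo:hi]
        neigh = neigh[~np.isnan(neigh)]
        if neigh.size and s <= np.min(neigh) and s <= -delta:
            candidates.append(i)
    boundaries: list[int] = []
    run: list[int] = []
    for i in candidates:
        if run and i == run[-1] + 1:
            run.append(i)
        else:
            if run:
                boundaries.append((run[0] + run[-1] + 1) // 2)
            run = [i]
    if run:
        boundaries.append((run[0] + run[-1] + 1) // 2)
    return scores, boundaries
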