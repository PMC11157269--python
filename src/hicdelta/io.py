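"""Readers and writers for the plain-text formats used across the pipeline.

All genomic coordinates are 0-based half-open internally.  The 4DN ``.pairs``
format is 1-based on disk, so positions are shifted on ingestion and restored
on output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

PAIRS_HEADER = "## pairs format v1.0"

PAIRS_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


class PairsParseError(ValueError):
    """Raised on a malformed ``.pairs`` line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 4DN ``.pairs`` file into a DataFrame with 0-based positions.

    An optional 8th column is interpreted as the uniqueness flag (``0``/``1``);
    if absent every pair is taken to be uniquely mapped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise PairsParseError(lineno, f"expected >=7 fields, got {len(fields)}")
            try:
                pos1 = int(fields[2]) - 1
                pos2 = int(fields[4]) - 1
            except ValueError as exc:
                raise PairsParseError(lineno, f"non-integer position: {exc}") from None
            s1, s2 = fields[5], fields[6]
            if s1 not in "+-" or s2 not in "+-":
                raise PairsParseError(lineno, f"bad strand fields {s1!r}/{s2!r}")
            unique = True
            if len(fields) >= 8:
                unique = fields[7] not in ("0", "false", "False")
            rows.append((fields[0], fields[1], pos1, fields[3], pos2, s1, s2, unique))
    df = pd.DataFrame(rows, columns=PAIRS_COLUMNS + ["unique"])
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    return df


def write_pairs(
    df: pd.DataFrame,
    path: str | Path,
    chrom_sizes: Mapping[str, int] | None = None,
) -> None:
    """Write pairs (0-based in memory) as a 4DN ``.pairs`` file (1-based)."""
    with open(path, "w") as fh:
        fh.write(PAIRS_HEADER + "\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2 unique\n")
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"#chromsize: {chrom} {size}\n")
        has_unique = "unique" in df.columns
        has_id = "readID" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            rid = getattr(row, "readID") if has_id else f"pair{i}"
            uniq = int(bool(getattr(row, "unique"))) if has_unique else 1
            fh.write(
                f"{rid}\t{row.chrom1}\t{row.pos1 + 1}\t{row.chrom2}\t{row.pos2 + 1}"
                f"\t{row.strand1}\t{row.strand2}\t{uniq}\n"
            )


def read_triplets(path: str | Path) -> pd.DataFrame:
    """Read a sparse contact table: ``bin1_start  bin2_start  count`` (bp)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["bin1_start", "bin2_start", "count"],
        dtype={"bin1_start": np.int64, "bin2_start": np.int64, "count": np.float64},
    )
    return df


def write_triplets(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_bedpe(
    df: pd.DataFrame,
    path: str | Path,
    chrom: str,
    resolution: int,
    score_columns: list[str] | None = None,
) -> None:
    """Write a loop table (``bin1``/``bin2`` bin indices) as BEDPE."""
    score_columns = score_columns or [
        c for c in df.columns if c not in ("bin1", "bin2", "chrom")
    ]
    with open(path, "w") as fh:
        header = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"] + score_columns
        fh.write("#" + "\t".join(header) + "\n")
        for row in df.itertuples(index=False):
            b1, b2 = int(row.bin1), int(row.bin2)
            fields = [
                chrom,
                str(b1 * resolution),
                str((b1 + 1) * resolution),
                chrom,
                str(b2 * resolution),
                str((b2 + 1) * resolution),
            ] + [f"{getattr(row, c):.6g}" if isinstance(getattr(row, c), float) else str(getattr(row, c)) for c in score_columns]
            fh.write("\t".join(fields) + "\n")


def read_digest(path: str | Path) -> dict[str, np.ndarray]:
    """Read a cut-site table (TSV: chrom, position) into per-chrom arrays."""
    cuts: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            cuts.setdefault(chrom, []).append(int(pos))
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in cuts.items()}


def write_digest(cuts: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in cuts.items():
            for pos in arr:
                fh.write(f"{chrom}\t{int(pos)}\n")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
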