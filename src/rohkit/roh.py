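"""Sliding-window detection of runs of homozygosity (ROH).

The caller re-implements the PLINK v1.9 ``--homozyg`` scanning scheme:

1. A window of ``window_snps`` consecutive SNPs slides one SNP at a time
   along each (individual, chromosome).  A window is *homozygous* iff it
   contains at most ``window_max_het`` heterozygous and at most
   ``window_max_missing`` missing calls.
2. Each SNP's *hit fraction* is the proportion of windows containing it
   that are homozygous; SNPs with hit fraction >= ``hit_threshold`` are
   "in run".
3. Maximal stretches of consecutive in-run SNPs form candidate segments,
   split wherever the physical gap between adjacent in-run SNPs exceeds
   ``max_gap``.
4. Candidates are kept iff they span at least ``min_snps`` SNPs, at least
   ``min_length`` bp, and at most ``min_density`` bp per SNP.

Window allowances are applied per *window*, not per run — the PLINK
semantics.  Segment coordinates are the positions of the first and last
member SNP (1-based inclusive), so ``length = end - start + 1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ROHParams",
    "ROHSegment",
    "window_scan",
    "call_roh",
    "classify_lengths",
    "chromosome_coverage",
    "sensitivity_sweep",
    "segments_to_frame",
    "frame_to_segments",
    "LENGTH_CLASSES",
]

#: length-class labels and half-open bp intervals [lo, hi)
LENGTH_CLASSES: list[tuple[str, float, float]] = [
    ("0-1 Mb", 0.0, 1e6),
    ("1-2 Mb", 1e6, 2e6),
    ("2-3 Mb", 2e6, 3e6),
    (">3 Mb", 3e6, np.inf),
]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH detection parameters (PLINK v1.9 defaults)."""

    window_snps: int = 50
    window_max_missing: int = 5
    window_max_het: int = 1
    min_snps: int = 50
    min_length: int = 100_000
    hit_threshold: float = 0.05
    max_gap: int = 1_000_000
    min_density: int = 50_000  # max bp per SNP inside a segment

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_snps < 0:
            raise ValueError("window_snps must be >= 1 and min_snps >= 0")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0 < self.hit_threshold <= 1:
            raise ValueError("hit_threshold must lie in (0, 1]")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window allowances must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity (coordinates 1-based inclusive)."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.n_snps < 1:
            raise ValueError("segment with no SNPs")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    df = pd.DataFrame(
        [dataclasses.asdict(s) | {"length_bp": s.length} for s in segments],
        columns=["individual", "chrom", "start", "end", "n_snps", "length_bp"],
    )
    return df


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    return [
        ROHSegment(str(r.individual), str(r.chrom), int(r.start), int(r.end), int(r.n_snps))
        for r in df.itertuples(index=False)
    ]


def window_scan(calls: np.ndarray, params: ROHParams = ROHParams()) -> np.ndarray:
    """Per-SNP hit fraction for one individual's calls on one chromosome.

    Returns an array of length ``len(calls)``; all zeros when the
    chromosome holds fewer SNPs than ``window_snps``.
    """
    calls = np.asarray(calls)
    S = calls.size
    W = params.window_snps
    frac = np.zeros(S, dtype=float)
    if S < W:
        return frac

    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    # windowed counts via cumulative sums: window k covers SNPs [k, k+W-1]
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(mis)))
    win_het = ch[W:] - ch[:-W]
    win_mis = cm[W:] - cm[:-W]
    win_ok = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)

    # SNP i is covered by windows k in [max(0, i-W+1), min(i, S-W)]
    cok = np.concatenate(([0], np.cumsum(win_ok.astype(np.int64))))
    i = np.arange(S)
    lo = np.maximum(0, i - W + 1)
    hi = np.minimum(i, S - W)
    n_win = hi - lo + 1
    n_hit = cok[hi + 1] - cok[lo]
    frac = n_hit / n_win
    return frac


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs of True in a boolean array."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def call_roh(
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Detect ROH for every individual on every chromosome of the panel."""
    segments: list[ROHSegment] = []
    for chrom in matrix.chromosomes():
        if chrom not in chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} absent from chromosome-length table")
        idx = matrix.chrom_slice(chrom)
        pos = matrix.sites["pos"].to_numpy()[idx]
        for s, sample in enumerate(matrix.samples):
            calls = matrix.calls[s, idx]
            frac = window_scan(calls, params)
            in_run = frac >= params.hit_threshold
            for a, b in _runs(in_run):
                # split where gap between adjacent in-run SNPs exceeds max_gap
                gaps = np.flatnonzero(np.diff(pos[a : b + 1]) > params.max_gap)
                bounds = [a] + [a + g + 1 for g in gaps] + [b + 1]
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    n_snps = hi - lo
                    start, end = int(pos[lo]), int(pos[hi - 1])
                    length = end - start + 1
                    if (
                        n_snps >= params.min_snps
                        and length >= params.min_length
                        and length / n_snps <= params.min_density
                    ):
                        segments.append(
                            ROHSegment(sample, chrom, start, end, n_snps)
                        )
    return segments


@dataclass
class ROHLengthSummary:
    """Per-length-class descriptive statistics of a segment set.

    ``pct_count`` is each class's share of the segment count;
    ``pct_cum_length`` its share of the cumulative ROH length (the two
    quantities a single "coverage" column is often ambiguously asked to
    carry).  Lengths are reported in Mb.
    """

    table: pd.DataFrame  # index: class labels + "total"

    @property
    def counts(self) -> pd.Series:
        return self.table["count"].drop("total")

    @property
    def total_count(self) -> int:
        return int(self.table.loc["total", "count"])


def classify_lengths(segments: list[ROHSegment]) -> ROHLengthSummary:
    """Stratify segments into the 0-1 / 1-2 / 2-3 / >3 Mb length classes.

    Class intervals are half-open, lower-inclusive (a 1 Mb segment falls in
    the 1-2 Mb class).  An empty segment list yields a table of zeros.
    """
    lengths = np.array([s.length for s in segments], dtype=float)
    total_n = lengths.size
    total_len = lengths.sum()
    rows = []
    for label, lo, hi in LENGTH_CLASSES:
        sel = lengths[(lengths >= lo) & (lengths < hi)]
        rows.append(
            {
                "class": label,
                "count": sel.size,
                "pct_count": 100 * sel.size / total_n if total_n else 0.0,
                "mean_length_mb": sel.mean() / 1e6 if sel.size else np.nan,
                "sd_length_mb": sel.std(ddof=0) / 1e6 if sel.size else np.nan,
                "pct_cum_length": 100 * sel.sum() / total_len if total_len else 0.0,
            }
        )
    rows.append(
        {
            "class": "total",
            "count": total_n,
            "pct_count": 100.0 if total_n else 0.0,
            "mean_length_mb": lengths.mean() / 1e6 if total_n else np.nan,
            "sd_length_mb": lengths.std(ddof=0) / 1e6 if total_n else np.nan,
            "pct_cum_length": 100.0 if total_len else 0.0,
        }
    )
    return ROHLengthSummary(pd.DataFrame(rows).set_index("class"))


def chromosome_coverage(
    segments: list[ROHSegment],
    chrom_lengths: dict[str, int],
    n_individuals: int,
) -> pd.Series:
    """Fraction of each chromosome covered by ROH, averaged over individuals.

    coverage(c) = sum of segment lengths on c over all individuals
    / (length of c * number of individuals).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    totals = {c: 0 for c in chrom_lengths}
    for s in segments:
        if s.chrom not in chrom_lengths:
            raise KeyError(f"chromosome {s.chrom!r} absent from chromosome-length table")
        totals[s.chrom] += s.length
    return pd.Series(
        {c: totals[c] / (chrom_lengths[c] * n_individuals) for c in chrom_lengths},
        name="roh_coverage",
    )


def sensitivity_sweep(
    matrix: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window_snps_grid=(50, 100, 150, 200),
    params: ROHParams = ROHParams(),
) -> pd.DataFrame:
    """Re-run the caller over a grid of window sizes.

    Returns a long-format table with one row per (window size, length
    class): count and percent of segments, mirroring a detection-parameter
    sensitivity analysis.  Only ``window_snps`` varies; all other
    parameters (including ``min_snps``) are held at ``params``.
    """
    grid = list(window_snps_grid)
    if grid != sorted(grid):
        raise ValueError("window_snps_grid must be ascending")
    rows = []
    for w in grid:
        p = dataclasses.replace(params, window_snps=w)
        summary = classify_lengths(call_roh(matrix, chrom_lengths, p)).table
        for label in summary.index:
            rows.append(
                {
                    "window_snps": w,
                    "class": label,
                    "count": int(summary.loc[label, "count"]),
                    "pct_count": summary.loc[label, "pct_count"],
                }
            )
    return pd.DataFrame(rows)
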