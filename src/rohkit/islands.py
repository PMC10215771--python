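"""ROH islands: per-SNP ROH incidence, top-percentile selection, gene overlap.

An ROH island (hotspot) is a genomic region where an unusually large
fraction of individuals carry a run of homozygosity — a classic footprint
of directional selection.  The scan follows the standard recipe: count,
for every SNP, how many individuals have an ROH spanning it; take the top
1% of SNPs by that incidence; merge nearby selected SNPs into islands and
report the genes they overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .roh import ROHSegment

__all__ = [
    "IslandRegion",
    "snp_incidence",
    "top_percentile_threshold",
    "merge_islands",
    "annotate_genes",
    "read_gene_intervals",
    "islands_to_frame",
]


@dataclass
class IslandRegion:
    """A contiguous top-incidence region (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    peak_incidence: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("island start > end")
        if self.n_snps < 1:
            raise ValueError("island with no SNPs")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def snp_incidence(
    segments: list[ROHSegment], sites: pd.DataFrame, n_individuals: int
) -> pd.DataFrame:
    """Per-SNP count and fraction of individuals whose ROH covers it.

    ``sites`` needs ``chrom`` and ``pos`` columns.  A SNP is covered by an
    individual iff one of that individual's segments on the same
    chromosome satisfies start <= pos <= end; segments of one individual
    are disjoint, so a plain accumulation never double-counts.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    chroms = sites["chrom"].to_numpy().astype(str)
    pos = sites["pos"].to_numpy()
    counts = np.zeros(len(sites), dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        delta = np.zeros(idx.size + 1, dtype=np.int64)
        for s in segments:
            if s.chrom != chrom:
                continue
            lo = np.searchsorted(cpos, s.start, side="left")
            hi = np.searchsorted(cpos, s.end, side="right")
            delta[lo] += 1
            delta[hi] -= 1
        counts[idx] = np.cumsum(delta[:-1])
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "count": counts,
            "incidence": counts / n_individuals,
        }
    )


def top_percentile_threshold(
    incidence: pd.DataFrame, top_fraction: float = 0.01
) -> tuple[float, pd.DataFrame]:
    """Empirical top-``top_fraction`` threshold and the selected SNP set.

    The threshold is the k-th largest incidence with k = ceil(n * f)
    (the lower order-statistic quantile); every SNP with incidence >= the
    threshold is selected, so ties at the threshold are all included and
    the selection may slightly exceed the nominal fraction.  If all
    incidences are equal the threshold is degenerate: a warning is emitted
    and every SNP is selected.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    vals = incidence["incidence"].to_numpy()
    n = vals.size
    if n == 0:
        raise ValueError("empty incidence table")
    if np.ptp(vals) == 0:
        warnings.warn(
            "all SNP incidences are equal; top-percentile threshold is degenerate "
            "and selects every SNP",
            stacklevel=2,
        )
        return float(vals[0]), incidence.copy()
    k = max(1, int(np.ceil(n * top_fraction)))
    threshold = float(np.sort(vals)[n - k])
    return threshold, incidence[vals >= threshold].copy()


def merge_islands(
    selected: pd.DataFrame, max_gap: int = 500_000, min_snps: int = 2
) -> list[IslandRegion]:
    """Cluster selected SNPs into islands.

    Consecutive selected SNPs on one chromosome at most ``max_gap`` bp
    apart belong to one island; islands with fewer than ``min_snps``
    members are dropped.  Island bounds are the first/last member SNP.
    """
    islands: list[IslandRegion] = []
    for chrom, grp in selected.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        inc = grp["incidence"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        bounds = [0] + list(breaks + 1) + [pos.size]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo < min_snps:
                continue
            islands.append(
                IslandRegion(
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    n_snps=hi - lo,
                    peak_incidence=float(inc[lo:hi].max()),
                )
            )
    return islands


def read_gene_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """Gene intervals as a frame (chrom, start, end, gene) — 1-based inclusive.

    BED input (0-based half-open) is shifted to 1-based inclusive; GFF3
    (already 1-based inclusive) is read through gffutils, keeping
    ``gene``-type features and their ID/Name attribute.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
            dtype={0: str},
        )
        df["start"] = df["start"].astype(np.int64) + 1  # 0-based -> 1-based
        df["end"] = df["end"].astype(np.int64)
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.features_of_type("gene"):
            name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
            rows.append({"chrom": feat.seqid, "start": feat.start, "end": feat.end, "gene": name})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if df.empty:
        warnings.warn("annotation contains no gene features", stacklevel=2)
    return df


def annotate_genes(
    islands: list[IslandRegion], genes: pd.DataFrame
) -> list[IslandRegion]:
    """Attach every gene overlapping each island by >= 1 bp (in place).

    ``genes`` is the frame produced by :func:`read_gene_intervals`.
    """
    trees: dict[str, IntervalTree] = {}
    for r in genes.itertuples(index=False):
        # IntervalTree is half-open; +1 makes the 1-based inclusive end interior
        trees.setdefault(str(r.chrom), IntervalTree()).addi(
            int(r.start), int(r.end) + 1, str(r.gene)
        )
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = sorted({iv.data for iv in tree.overlap(isl.start, isl.end + 1)}) if tree else []
        isl.genes = hits
    return islands


def islands_to_frame(islands: list[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": i.chrom,
                "start": i.start,
                "end": i.end,
                "length_bp": i.length,
                "n_snps": i.n_snps,
                "peak_incidence": i.peak_incidence,
                "genes": ",".join(i.genes),
            }
            for i in islands
        ],
        columns=["chrom", "start", "end", "length_bp", "n_snps", "peak_incidence", "genes"],
    )
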