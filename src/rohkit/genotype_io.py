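"""Genotype container, VCF I/O and panel quality control.

The package works on an individuals x sites matrix of biallelic SNP
genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt, ``MISSING`` = no call).
Reading goes through cyvcf2/htslib; writing emits a minimal text VCF v4.2
that round-trips losslessly through :func:`read_vcf`.

Coordinates are 1-based inclusive everywhere (VCF convention).  Sites are
kept sorted by (chromosome, position), where chromosomes stay in their
first-appearance order — lexicographic sorting would place "10" before "2".
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCParams",
    "QCReport",
    "VCFParseError",
    "QCError",
    "read_vcf",
    "write_vcf",
    "qc_filter",
    "read_chrom_lengths",
]

#: Sentinel genotype code for a missing call.
MISSING: int = -1

_SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]
_NUCLEOTIDES = frozenset("ACGT")


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


class QCError(ValueError):
    """Raised when quality control empties the panel."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for a sample panel.

    Parameters
    ----------
    samples
        Ordered individual identifiers.
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based),
        ``ref``/``alt`` (single nucleotides) and ``qual`` (float32,
        NaN when absent), one row per site.
    calls
        ``int8`` array of shape (n_samples, n_sites) with values in
        {0, 1, 2, MISSING}.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(self.sites) and list(self.sites.columns[:5]) != _SITE_COLUMNS:
            missing = [c for c in _SITE_COLUMNS if c not in self.sites.columns]
            if missing:
                raise ValueError(f"sites missing columns {missing}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,MISSING}")
        self._sort_sites()

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in their stored (first-appearance) order."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Indices of the sites on one chromosome (sorted by position)."""
        return np.flatnonzero(self.sites["chrom"].to_numpy() == chrom)

    def _sort_sites(self) -> None:
        if not len(self.sites):
            return
        chroms = self.sites["chrom"].astype(str)
        order_key = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
        idx = np.lexsort(
            (self.sites["pos"].to_numpy(), chroms.map(order_key).to_numpy())
        )
        if not np.array_equal(idx, np.arange(len(idx))):
            self.sites = self.sites.iloc[idx].reset_index(drop=True)
            self.calls = self.calls[:, idx]
        pos = self.sites["pos"].to_numpy()
        # strictly increasing positions within each chromosome
        same = np.diff(self.sites["chrom"].astype(str).map(order_key).to_numpy()) == 0
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("duplicate or non-increasing positions within a chromosome")
        if (pos < 1).any():
            raise ValueError("positions must be >= 1")

    # -- derived per-site summaries ---------------------------------------

    def nonmissing_counts(self) -> np.ndarray:
        """Per-site count of individuals with a call."""
        return (self.calls != MISSING).sum(axis=0)

    def alt_frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        alt = np.where(obs, self.calls, 0).sum(axis=0, dtype=np.int64)
        an = 2 * obs.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore"):
            return np.where(an > 0, alt / np.maximum(an, 1), np.nan)

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        site_idx = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            sites=self.sites.iloc[site_idx],
            calls=self.calls[np.ix_(sample_idx, site_idx)],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.sites[["chrom", "pos", "ref", "alt"]].equals(
                other.sites[["chrom", "pos", "ref", "alt"]]
            )
            and np.array_equal(
                self.sites["qual"].to_numpy(),
                other.sites["qual"].to_numpy(),
                equal_nan=True,
            )
        )


@dataclass(frozen=True)
class QCParams:
    """Site- and individual-level filtering thresholds.

    Defaults follow common whole-genome SNP panel practice: MAF >= 0.05,
    site missing rate <= 0.1, individual call rate >= 0.9, site quality >= 30.
    """

    maf_min: float = 0.05
    site_missing_max: float = 0.1
    indiv_call_min: float = 0.9
    qual_min: float = 30.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "site_missing_max", "indiv_call_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Counts removed by each filter, in application order."""

    n_samples_in: int
    n_sites_in: int
    n_indiv_removed_callrate: int
    n_sites_removed_qual: int
    n_sites_removed_missing: int
    n_sites_removed_maf: int
    n_samples_out: int
    n_sites_out: int
    params: QCParams
    order: str = "individuals filtered on raw panel first, then sites (qual, missing rate, MAF) on remaining individuals"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("params")
        d.pop("order")
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})


# ---------------------------------------------------------------------------
# VCF reading / writing


def _is_biallelic_snp(ref: str, alts) -> bool:
    if alts is None or len(alts) != 1:
        return False
    alt = alts[0]
    return (
        len(ref) == 1
        and len(alt) == 1
        and ref.upper() in _NUCLEOTIDES
        and alt.upper() in _NUCLEOTIDES
    )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are silently dropped.  Genotypes are
    parsed phase-insensitively; half-calls (e.g. ``./1``) become MISSING;
    haploid GT entries raise :class:`VCFParseError`.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise VCFParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VCFParseError(f"{path}: VCF contains zero samples")

    rows: list[tuple] = []
    codes: list[np.ndarray] = []
    for rec_no, rec in enumerate(vcf, start=1):
        try:
            if not _is_biallelic_snp(rec.REF, rec.ALT):
                continue
            gts = rec.genotypes
            site_codes = np.empty(len(samples), dtype=np.int8)
            for j, gt in enumerate(gts):
                if len(gt) == 2:  # single allele + phase flag => haploid call
                    raise VCFParseError(
                        f"{path}: record {rec_no} ({rec.CHROM}:{rec.POS}): "
                        f"haploid genotype for sample {samples[j]}"
                    )
                a1, a2 = gt[0], gt[1]
                site_codes[j] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
            qual = np.float32(rec.QUAL) if rec.QUAL is not None else np.float32(np.nan)
            rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], qual))
            codes.append(site_codes)
        except VCFParseError:
            raise
        except Exception as exc:
            raise VCFParseError(f"{path}: record {rec_no}: {exc}") from exc

    sites = pd.DataFrame(rows, columns=_SITE_COLUMNS)
    if len(sites):
        sites["pos"] = sites["pos"].astype(np.int64)
        sites["qual"] = sites["qual"].astype(np.float32)
    else:
        sites = sites.astype({"pos": np.int64, "qual": np.float32}, errors="ignore")
    calls = (
        np.stack(codes, axis=1) if codes else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (``read_vcf`` of the output equals the input)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chromosomes():
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + matrix.samples) + "\n")
        quals = matrix.sites["qual"].to_numpy()
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            q = "." if np.isnan(quals[i]) else f"{float(quals[i]):g}"
            fields = [
                str(row.chrom), str(row.pos), ".", row.ref, row.alt, q, ".", ".", "GT",
            ]
            fields += [_CODE_TO_GT[int(c)] for c in matrix.calls[:, i]]
            fh.write("\t".join(fields) + "\n")


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a ``chrom<TAB>length_bp`` table into an ordered dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length_bp"],
                     dtype={"chrom": str}, comment="#")
    if (df["length_bp"] <= 0).any():
        raise ValueError(f"{path}: non-positive chromosome length")
    return dict(zip(df["chrom"], df["length_bp"].astype(int)))


# ---------------------------------------------------------------------------
# Quality control

_EPS = 1e-9  # guards float threshold comparisons on exact-fraction boundaries


def qc_filter(
    matrix: GenotypeMatrix,
    params: QCParams = QCParams(),
    autosomes: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply individual- then site-level filters.

    Individuals with call rate below ``indiv_call_min`` (computed on the raw
    panel) are removed first; then sites failing quality (< ``qual_min``,
    only where QUAL is present), site missing rate (> ``site_missing_max``)
    or MAF (< ``maf_min``) on the remaining individuals.  MAF uses
    non-missing alleles only in the denominator; all thresholds are
    inclusive as written (MAF exactly at ``maf_min`` is kept).

    ``autosomes`` optionally restricts the panel to a chromosome whitelist
    before any filtering.
    """
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise QCError("cannot QC an empty matrix")
    if autosomes is not None:
        keep = np.flatnonzero(matrix.sites["chrom"].isin(list(autosomes)).to_numpy())
        matrix = matrix.subset(site_idx=keep)
        if matrix.n_sites == 0:
            raise QCError("no sites on the requested autosomes")

    n_samples_in, n_sites_in = matrix.n_samples, matrix.n_sites
    obs = matrix.calls != MISSING

    call_rate = obs.sum(axis=1) / n_sites_in
    keep_ind = call_rate + _EPS >= params.indiv_call_min
    n_ind_removed = int((~keep_ind).sum())
    if not keep_ind.any():
        raise QCError("all individuals removed by call-rate filter")
    m = matrix.subset(sample_idx=np.flatnonzero(keep_ind))

    obs = m.calls != MISSING
    n_obs = obs.sum(axis=0, dtype=np.int64)

    quals = m.sites["qual"].to_numpy(dtype=float)
    fail_qual = ~np.isnan(quals) & (quals + _EPS < params.qual_min)

    miss = (m.n_samples - n_obs) / m.n_samples
    fail_miss = miss > params.site_missing_max + _EPS

    alt = np.where(obs, m.calls, 0).sum(axis=0, dtype=np.int64)
    an = 2 * n_obs
    min_ac = np.minimum(alt, an - alt)
    fail_maf = (min_ac + _EPS < params.maf_min * an) | (an == 0)

    # attribute each removed site to the first failing criterion, in order
    n_fail_qual = int(fail_qual.sum())
    n_fail_miss = int((fail_miss & ~fail_qual).sum())
    n_fail_maf = int((fail_maf & ~fail_qual & ~fail_miss).sum())
    keep_site = ~(fail_qual | fail_miss | fail_maf)
    if not keep_site.any():
        raise QCError("all sites removed: panel empty after QC")
    out = m.subset(site_idx=np.flatnonzero(keep_site))

    report = QCReport(
        n_samples_in=n_samples_in,
        n_sites_in=n_sites_in,
        n_indiv_removed_callrate=n_ind_removed,
        n_sites_removed_qual=n_fail_qual,
        n_sites_removed_missing=n_fail_miss,
        n_sites_removed_maf=n_fail_maf,
        n_samples_out=out.n_samples,
        n_sites_out=out.n_sites,
        params=params,
    )
    return out, report
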