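"""Genetic-diversity indices and linkage-disequilibrium decay.

Per-site statistics for a QC-passed biallelic panel with alt-allele
frequency ``p`` and non-missing sample count ``n``:

* observed heterozygosity  H_O = (# het calls) / n
* expected heterozygosity  H_E = 2 p (1 - p)   (sample frequency, no
  small-sample correction — the PLINK convention)
* minor allele frequency   MAF = min(p, 1 - p)
* nucleotide diversity     pi = 2 p (1 - p) * 2n / (2n - 1), the unbiased
  per-site estimator for a biallelic SNP (the VCFtools definition)

P_N is the fraction of sites that are polymorphic (MAF > 0).

LD is measured as the squared Pearson correlation of genotype dosages
across individuals with both calls present (the Rogers–Huff composite-LD
estimator for unphased data, as used by PopLDdecay), binned by physical
distance within chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["DiversityResult", "LDDecayCurve", "per_site_stats", "maf_spectrum", "ld_decay"]


@dataclass
class DiversityResult:
    """Per-site diversity vectors plus over-sites summary (means ± SD).

    The ``±`` summaries are standard deviations over sites.
    """

    per_site: pd.DataFrame  # chrom, pos, maf, ho, he, pi
    ho_mean: float
    ho_sd: float
    he_mean: float
    he_sd: float
    maf_mean: float
    maf_sd: float
    pi_mean: float
    pi_sd: float
    p_n: float
    n_sites: int
    n_excluded_sites: int  # zero non-missing calls

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": ["H_E", "H_O", "P_N", "MAF", "pi"],
                "mean": [self.he_mean, self.ho_mean, self.p_n, self.maf_mean, self.pi_mean],
                "sd": [self.he_sd, self.ho_sd, np.nan, self.maf_sd, self.pi_sd],
            }
        )


@dataclass
class LDDecayCurve:
    bin_start: np.ndarray  # bp, inclusive
    bin_end: np.ndarray  # bp, exclusive
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    n_skipped_pairs: int = 0  # zero-variance pairs (undefined r^2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_start,
                "bin_end": self.bin_end,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def per_site_stats(matrix: GenotypeMatrix) -> DiversityResult:
    """Compute H_O, H_E, MAF and pi per site and their over-sites summary.

    Sites with zero non-missing calls are excluded from the vectors and
    counted in ``n_excluded_sites``.
    """
    obs = matrix.calls != MISSING
    n = obs.sum(axis=0, dtype=np.int64)
    keep = n > 0
    n_excluded = int((~keep).sum())

    het = ((matrix.calls == 1) & obs).sum(axis=0, dtype=np.int64)
    alt = np.where(obs, matrix.calls, 0).sum(axis=0, dtype=np.int64)

    n = n[keep]
    het = het[keep]
    alt = alt[keep]
    p = alt / (2 * n)

    ho = het / n
    he = 2 * p * (1 - p)
    maf = np.minimum(p, 1 - p)
    pi = he * (2 * n) / (2 * n - 1)

    per_site = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"].to_numpy()[keep],
            "pos": matrix.sites["pos"].to_numpy()[keep],
            "maf": maf,
            "ho": ho,
            "he": he,
            "pi": pi,
        }
    )
    return DiversityResult(
        per_site=per_site,
        ho_mean=float(ho.mean()),
        ho_sd=float(ho.std(ddof=0)),
        he_mean=float(he.mean()),
        he_sd=float(he.std(ddof=0)),
        maf_mean=float(maf.mean()),
        maf_sd=float(maf.std(ddof=0)),
        pi_mean=float(pi.mean()),
        pi_sd=float(pi.std(ddof=0)),
        p_n=float((maf > 0).mean()),
        n_sites=int(keep.sum()),
        n_excluded_sites=n_excluded,
    )


def maf_spectrum(maf_per_site: np.ndarray, thresholds=(0.10, 0.40)) -> pd.DataFrame:
    """Fraction of sites below / above each MAF threshold.

    Returns one row per threshold with columns ``threshold``,
    ``frac_below`` (MAF < t) and ``frac_above`` (MAF > t).
    """
    maf = np.asarray(maf_per_site, dtype=float)
    if maf.size == 0:
        raise ValueError("empty MAF vector")
    if maf.min() < 0 or maf.max() > 0.5 + 1e-12:
        raise ValueError("MAF values must lie in [0, 0.5]")
    rows = [
        {
            "threshold": float(t),
            "frac_below": float((maf < t).mean()),
            "frac_above": float((maf > t).mean()),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def ld_decay(
    matrix: GenotypeMatrix, max_dist: int = 300_000, n_bins: int = 100
) -> LDDecayCurve:
    """Mean dosage-r² by physical distance, pooled over chromosomes.

    For every intra-chromosomal site pair at distance <= ``max_dist``,
    r² is the squared Pearson correlation of dosages over individuals with
    both calls non-missing.  Pairs where either site has zero variance on
    the shared individuals are skipped and counted.
    """
    edges = np.linspace(0, max_dist, n_bins + 1)
    sum_r2 = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0

    any_pair = False
    for chrom in matrix.chromosomes():
        idx = matrix.chrom_slice(chrom)
        if idx.size < 2:
            continue
        any_pair = True
        pos = matrix.sites["pos"].to_numpy()[idx]
        G = matrix.calls[:, idx].astype(float)
        valid = G != MISSING
        G0 = np.where(valid, G, 0.0)
        V = valid.astype(float)

        for lag in range(1, idx.size):
            d = pos[lag:] - pos[:-lag]
            if d.min() > max_dist:
                break
            in_range = d <= max_dist
            if not in_range.any():
                continue
            A, B = G0[:, :-lag], G0[:, lag:]
            VA, VB = V[:, :-lag], V[:, lag:]
            W = VA * VB
            n = W.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sa = (A * W).sum(axis=0)
                sb = (B * W).sum(axis=0)
                saa = (A * A * W).sum(axis=0)
                sbb = (B * B * W).sum(axis=0)
                sab = (A * B * W).sum(axis=0)
                cov = sab - sa * sb / n
                va = saa - sa * sa / n
                vb = sbb - sb * sb / n
                r2 = cov * cov / (va * vb)
            ok = in_range & (n >= 2) & (va > 1e-12) & (vb > 1e-12)
            n_skipped += int((in_range & ~ok).sum())
            if not ok.any():
                continue
            b = np.minimum(
                np.searchsorted(edges, d[ok], side="right") - 1, n_bins - 1
            )
            b = np.maximum(b, 0)
            np.add.at(sum_r2, b, r2[ok])
            np.add.at(n_pairs, b, 1)

    if not any_pair:
        raise ValueError("LD decay needs >= 2 sites on at least one chromosome")

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(n_pairs > 0, sum_r2 / np.maximum(n_pairs, 1), np.nan)
    return LDDecayCurve(
        bin_start=edges[:-1].astype(np.int64),
        bin_end=edges[1:].astype(np.int64),
        mean_r2=mean_r2,
        n_pairs=n_pairs,
        n_skipped_pairs=n_skipped,
    )
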