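"""Genomic inbreeding coefficients: F_ROH, F_HOM and F_GRM.

Three complementary estimators of individual inbreeding from a SNP panel:

* **F_ROH** — total ROH length divided by the autosomal genome length
  covered by the markers (``l_auto``), optionally decomposed by ROH length
  class.  The class components sum to the total exactly because the length
  classes partition the segments.
* **F_HOM** — excess homozygosity, (O - E)/(L - E), where O is the
  observed homozygote count over an individual's non-missing sites, L the
  non-missing site count, and E the expected homozygote count under
  Hardy–Weinberg using sample allele frequencies with the 2n/(2n-1)
  small-sample correction (the PLINK ``--het`` convention).  May be
  negative.
* **F_GRM** — G_jj - 1, the diagonal of the VanRaden method-1 genomic
  relationship matrix G = ZZ' / (2 Σ p_i (1 - p_i)) built from centred
  dosages z_ij = d_ij - 2 p_i, with missing dosages mean-imputed to 2 p_i.
  May be negative.

Allele frequencies are in-sample throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .roh import LENGTH_CLASSES, ROHSegment

__all__ = [
    "f_roh",
    "f_hom",
    "grm_vanraden",
    "f_grm",
    "inbreeding_table",
    "estimator_summary",
    "F_ROH_CLASS_COLUMNS",
    "DEFAULT_L_AUTO",
]

#: autosomal genome length conventionally used for chicken panels (900 Mb)
DEFAULT_L_AUTO: int = 900_000_000

F_ROH_CLASS_COLUMNS = ["f_roh_0_1mb", "f_roh_1_2mb", "f_roh_2_3mb", "f_roh_gt3mb"]


def f_roh(
    segments: list[ROHSegment], l_auto: int = DEFAULT_L_AUTO
) -> tuple[float, dict[str, float]]:
    """F_ROH for one individual: (total, per-length-class decomposition).

    The total is computed as the sum of the class components, so the
    additivity identity holds exactly in floating point.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    by_class: dict[str, float] = {}
    for col, (label, lo, hi) in zip(F_ROH_CLASS_COLUMNS, LENGTH_CLASSES):
        tot = 0
        for s in segments:
            if s.length > l_auto:
                raise ValueError(
                    f"segment of {s.length} bp exceeds l_auto={l_auto} bp"
                )
            if lo <= s.length < hi:
                tot += s.length
        by_class[col] = tot / l_auto
    total = sum(by_class.values())
    return total, by_class


def f_hom(matrix: GenotypeMatrix) -> pd.Series:
    """Per-individual excess-homozygosity coefficient (O - E)/(L - E).

    Individuals with zero non-missing sites get NaN.
    """
    obs = matrix.calls != MISSING
    n = obs.sum(axis=0, dtype=np.int64)  # per-site non-missing count
    alt = np.where(obs, matrix.calls, 0).sum(axis=0, dtype=np.int64)
    ok = n > 0
    p = np.zeros(matrix.n_sites)
    p[ok] = alt[ok] / (2 * n[ok])
    # expected per-site homozygosity under HWE with small-sample correction
    exp_hom = np.zeros(matrix.n_sites)
    exp_hom[ok] = 1.0 - 2.0 * p[ok] * (1.0 - p[ok]) * (2 * n[ok]) / (2 * n[ok] - 1)

    values = np.full(matrix.n_samples, np.nan)
    hom = (matrix.calls == 0) | (matrix.calls == 2)
    for j in range(matrix.n_samples):
        mask = obs[j] & ok
        L = int(mask.sum())
        if L == 0:
            continue
        O = int((hom[j] & mask).sum())
        E = float(exp_hom[mask].sum())
        denom = L - E
        values[j] = (O - E) / denom if abs(denom) > 1e-12 else np.nan
    return pd.Series(values, index=matrix.samples, name="f_hom")


def grm_vanraden(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """VanRaden method-1 genomic relationship matrix.

    Returns ``(G, p)`` with G of shape (n, n) and p the in-sample
    alt-allele frequencies used.  Monomorphic sites are rejected — QC is
    expected to have removed them.
    """
    p = matrix.alt_frequencies()
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("GRM requires polymorphic sites with p in (0,1); run QC first")
    D = matrix.calls.astype(float)
    obs = matrix.calls != MISSING
    D[~obs] = np.nan
    Z = np.where(obs, D - 2 * p, 0.0)  # missing dosages imputed to 2p => 0 centred
    denom = 2.0 * float(np.sum(p * (1 - p)))
    G = Z @ Z.T / denom
    return G, p


def f_grm(matrix: GenotypeMatrix) -> pd.Series:
    """Per-individual F_GRM = G_jj - 1 from the VanRaden method-1 GRM."""
    G, _ = grm_vanraden(matrix)
    return pd.Series(np.diag(G) - 1.0, index=matrix.samples, name="f_grm")


def inbreeding_table(
    matrix: GenotypeMatrix,
    segments: list[ROHSegment],
    l_auto: int = DEFAULT_L_AUTO,
) -> pd.DataFrame:
    """All seven per-individual coefficients in one tidy frame.

    Columns: the four per-class F_ROH components, ``f_roh_all``,
    ``f_hom`` and ``f_grm``; one row per individual of the panel (an
    individual with no ROH has zero F_ROH).
    """
    by_ind: dict[str, list[ROHSegment]] = {s: [] for s in matrix.samples}
    for seg in segments:
        if seg.individual not in by_ind:
            raise KeyError(f"segment for unknown individual {seg.individual!r}")
        by_ind[seg.individual].append(seg)

    rows = []
    for sample in matrix.samples:
        total, by_class = f_roh(by_ind[sample], l_auto)
        rows.append({"individual": sample, **by_class, "f_roh_all": total})
    df = pd.DataFrame(rows).set_index("individual")
    df["f_hom"] = f_hom(matrix)
    df["f_grm"] = f_grm(matrix)
    return df


def estimator_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± SD per estimator plus their Pearson correlation matrix.

    Requires at least 3 individuals.  Constant columns yield NaN
    correlations (undefined, not zero).
    """
    if len(table) < 3:
        raise ValueError("estimator summary needs >= 3 individuals")
    summary = pd.DataFrame(
        {
            "mean": table.mean(),
            "sd": table.std(ddof=1),
            "min": table.min(),
            "max": table.max(),
        }
    )
    corr = table.corr(method="pearson", min_periods=3)
    return summary, corr
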