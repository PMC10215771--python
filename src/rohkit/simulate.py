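"""Pedigree gene-dropping simulator with ground-truth autozygosity.

Founder haplotypes in linkage equilibrium are dropped through a pedigree
with Poisson recombination (no interference); every chromosome copy
carries a persistent ancestral-haplotype label, so the true autozygous
segments of each individual — the intervals where both carried labels
descend from the same founder haplotype — are known exactly, alongside the
pedigree-expected inbreeding coefficient F_ped.  Genotyping error and
missingness are applied last.

This makes every pipeline stage testable with a known answer: ROH callers
against the true autozygous tracts, inbreeding estimators against F_ped.

Default scale (2 chromosomes x 20 Mb, 4,000 SNPs per chromosome — one SNP
per 5 kb) keeps a 60-individual cohort inside a few seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_vcf
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "FounderPool",
    "SimTruth",
    "simulate_founders",
    "gene_drop",
    "add_noise",
    "simulate_panel",
    "emit",
    "full_sib_pedigree",
    "mixed_pedigree",
]

# one gamete = list of (start_bp, end_bp, ancestral haplotype label),
# contiguous 1-based inclusive intervals covering the whole chromosome
Gamete = list[tuple[int, int, int]]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; ``seed`` fixes every source of randomness."""

    n_chrom: int = 2
    chrom_length: int = 20_000_000  # bp
    n_sites: int = 4_000  # per chromosome
    maf_lo: float = 0.05  # founder alt-frequency ~ U(maf_lo, maf_hi)
    maf_hi: float = 0.5
    recomb_cm_per_mb: float = 3.0
    error_rate: float = 1e-3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_lo <= self.maf_hi <= 1:
            raise ValueError(f"need 0 <= maf_lo <= maf_hi <= 1, got [{self.maf_lo}, {self.maf_hi}]")
        for name in ("error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.n_sites < 1 or self.n_chrom < 1 or self.chrom_length < 1:
            raise ValueError("n_chrom, chrom_length and n_sites must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chrom)]

    @property
    def morgans_per_chrom(self) -> float:
        return self.chrom_length / 1e6 * self.recomb_cm_per_mb / 100.0

    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length


@dataclass
class FounderPool:
    """Founder haplotype alleles, site table and per-site alt frequencies."""

    sites: pd.DataFrame  # chrom, pos, ref, alt, qual
    freqs: np.ndarray  # alt frequency per site
    alleles: np.ndarray  # (2 * n_founders, n_total_sites) of 0/1
    founder_ids: list[str]

    def hap_label(self, founder_index: int, copy: int) -> int:
        return 2 * founder_index + copy


@dataclass
class SimTruth:
    """Ground truth: pedigree F plus realized autozygous segments."""

    f_ped: pd.Series  # per individual
    segments: pd.DataFrame  # individual, chrom, start, end (1-based inclusive)
    genome_length: int

    def autozygous_fraction(self) -> pd.Series:
        """Realized fraction of the genome that is autozygous, per individual."""
        frac = pd.Series(0.0, index=self.f_ped.index, name="autozygous_fraction")
        if len(self.segments):
            lengths = self.segments["end"] - self.segments["start"] + 1
            per_ind = lengths.groupby(self.segments["individual"]).sum()
            frac.loc[per_ind.index] = per_ind / self.genome_length
        return frac


def simulate_founders(config: SimConfig, n_founders: int, rng=None) -> FounderPool:
    """Draw site positions, allele frequencies and founder haplotypes.

    Positions are uniform within each chromosome (sorted, deduplicated —
    the realized site count can fall slightly below ``n_sites``); founder
    haplotypes are drawn independently per site, i.e. founders are in
    linkage equilibrium, and each chromosome copy gets a unique label.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for chrom in config.chromosomes:
        pos = np.unique(rng.integers(1, config.chrom_length + 1, size=config.n_sites))
        for p in pos:
            rows.append((chrom, int(p)))
    sites = pd.DataFrame(rows, columns=["chrom", "pos"])
    n_total = len(sites)
    refalt = rng.integers(0, 4, size=(n_total, 2))
    nts = np.array(list("ACGT"))
    sites["ref"] = nts[refalt[:, 0]]
    sites["alt"] = nts[(refalt[:, 0] + 1 + refalt[:, 1] % 3) % 4]
    sites["qual"] = np.float32(60.0)

    freqs = rng.uniform(config.maf_lo, config.maf_hi, size=n_total)
    alleles = (rng.random((2 * n_founders, n_total)) < freqs).astype(np.int8)
    return FounderPool(
        sites=sites,
        freqs=freqs,
        alleles=alleles,
        founder_ids=[],
    )


def _meiosis(hap_a: Gamete, hap_b: Gamete, length: int, morgans: float, rng) -> Gamete:
    """Recombine a parent's two chromosome copies into one gamete."""
    n_x = rng.poisson(morgans)
    cuts = sorted(set(int(x) for x in rng.integers(2, length + 1, size=n_x)))
    current = int(rng.integers(0, 2))
    sources = (hap_a, hap_b)
    out: Gamete = []
    start = 1
    for cut in cuts + [length + 1]:
        end = cut - 1
        if end >= start:
            for s, e, lab in sources[current]:
                lo, hi = max(s, start), min(e, end)
                if lo <= hi:
                    if out and out[-1][2] == lab and out[-1][1] == lo - 1:
                        out[-1] = (out[-1][0], hi, lab)
                    else:
                        out.append((lo, hi, lab))
        current = 1 - current
        start = cut
    return out


def _autozygous_intervals(hap_a: Gamete, hap_b: Gamete) -> list[tuple[int, int]]:
    """Intervals where the two gametes carry the same ancestral label."""
    out: list[tuple[int, int]] = []
    for sa, ea, la in hap_a:
        for sb, eb, lb in hap_b:
            if la == lb:
                lo, hi = max(sa, sb), min(ea, eb)
                if lo <= hi:
                    if out and out[-1][1] == lo - 1:
                        out[-1] = (out[-1][0], hi)
                    else:
                        out.append((lo, hi))
    out.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in out:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def gene_drop(
    pedigree: Pedigree, founders: FounderPool, config: SimConfig, rng=None
) -> tuple[GenotypeMatrix, SimTruth]:
    """Drop founder haplotypes through the pedigree.

    Returns the noise-free genotype matrix plus the ground truth (F_ped and
    realized autozygous segments).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    founder_list = pedigree.founders()
    if 2 * len(founder_list) > founders.alleles.shape[0]:
        raise ValueError("founder pool smaller than the pedigree's founder count")
    founder_index = {f: i for i, f in enumerate(founder_list)}

    chroms = config.chromosomes
    sites = founders.sites
    site_idx = {c: np.flatnonzero(sites["chrom"].to_numpy() == c) for c in chroms}
    site_pos = {c: sites["pos"].to_numpy()[site_idx[c]] for c in chroms}

    # genome[ind][chrom] = (maternal gamete, paternal gamete)
    genome: dict[str, dict[str, tuple[Gamete, Gamete]]] = {}
    truth_rows = []
    for ind in pedigree.individuals:
        sire, dam = pedigree.parents[ind]
        genome[ind] = {}
        for chrom in chroms:
            L = config.chrom_length
            if sire is None:
                fi = founder_index[ind]
                g1: Gamete = [(1, L, founders.hap_label(fi, 0))]
                g2: Gamete = [(1, L, founders.hap_label(fi, 1))]
            else:
                g1 = _meiosis(*genome[sire][chrom], L, config.morgans_per_chrom, rng)
                g2 = _meiosis(*genome[dam][chrom], L, config.morgans_per_chrom, rng)
            genome[ind][chrom] = (g1, g2)
            for lo, hi in _autozygous_intervals(g1, g2):
                truth_rows.append(
                    {"individual": ind, "chrom": chrom, "start": lo, "end": hi}
                )

    # paint alleles onto sites
    individuals = pedigree.individuals
    calls = np.empty((len(individuals), len(sites)), dtype=np.int8)
    for i, ind in enumerate(individuals):
        for chrom in chroms:
            idx = site_idx[chrom]
            pos = site_pos[chrom]
            dosage = np.zeros(idx.size, dtype=np.int8)
            for gam in genome[ind][chrom]:
                for s, e, lab in gam:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    dosage[lo:hi] += founders.alleles[lab, idx[lo:hi]]
            calls[i, idx] = dosage

    matrix = GenotypeMatrix(samples=individuals, sites=sites.copy(), calls=calls)
    truth = SimTruth(
        f_ped=pedigree.inbreeding_table(),
        segments=pd.DataFrame(
            truth_rows, columns=["individual", "chrom", "start", "end"]
        ),
        genome_length=config.genome_length,
    )
    return matrix, truth


def add_noise(
    matrix: GenotypeMatrix, error_rate: float, missing_rate: float, seed: int
) -> GenotypeMatrix:
    """Flip calls to a uniformly chosen different code with probability
    ``error_rate``, then drop calls to MISSING with probability
    ``missing_rate``; both independent per call."""
    if not (0 <= error_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0,1]")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    flip = rng.random(calls.shape) < error_rate
    if flip.any():
        shift = rng.integers(1, 3, size=int(flip.sum()))  # +1 or +2 mod 3
        present = calls[flip] != MISSING
        new = calls[flip].astype(np.int64)
        new[present] = (new[present] + shift[present]) % 3
        calls[flip] = new.astype(np.int8)
    drop = rng.random(calls.shape) < missing_rate
    calls[drop] = MISSING
    return GenotypeMatrix(samples=list(matrix.samples), sites=matrix.sites.copy(), calls=calls)


def simulate_panel(
    pedigree: Pedigree, config: SimConfig = SimConfig()
) -> tuple[GenotypeMatrix, SimTruth]:
    """Founders -> gene drop -> noise, all driven by ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    s_founders, s_drop, s_noise = root.spawn(3)
    founders = simulate_founders(
        config, len(pedigree.founders()), rng=np.random.default_rng(s_founders)
    )
    matrix, truth = gene_drop(
        pedigree, founders, config, rng=np.random.default_rng(s_drop)
    )
    noise_seed = int(s_noise.generate_state(1)[0] % (2**31))
    matrix = add_noise(matrix, config.error_rate, config.missing_rate, noise_seed)
    return matrix, truth


def emit(matrix: GenotypeMatrix, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write the simulated panel (VCF) and truth tables (TSV) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "truth_f": outdir / "truth_f.tsv",
        "truth_segments": outdir / "truth_segments.tsv",
    }
    write_vcf(matrix, paths["vcf"])
    truth.f_ped.rename_axis("individual").reset_index().to_csv(
        paths["truth_f"], sep="\t", index=False
    )
    truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Caller-benchmark panels with implanted homozygous tracts


def implant_tracts(matrix: GenotypeMatrix, tracts: pd.DataFrame) -> GenotypeMatrix:
    """Force homozygosity (hom-ref) over given per-individual intervals.

    ``tracts`` columns: individual, chrom, start, end (1-based inclusive).
    Returns a new matrix; useful for building caller benchmarks with known
    homozygous segments on an arbitrary background panel.
    """
    calls = matrix.calls.copy()
    chroms = matrix.sites["chrom"].to_numpy().astype(str)
    pos = matrix.sites["pos"].to_numpy()
    index = {s: i for i, s in enumerate(matrix.samples)}
    for t in tracts.itertuples(index=False):
        sel = (chroms == str(t.chrom)) & (pos >= t.start) & (pos <= t.end)
        calls[index[str(t.individual)], sel] = 0
    return GenotypeMatrix(list(matrix.samples), matrix.sites.copy(), calls)


#: tract length-class recipe for :func:`sweep_benchmark_panel` —
#: composition dominated by short tracts, as in livestock WGS cohorts;
#: length ranges keep a >=0.1 Mb margin from every class boundary so the
#: benchmark measures detection, not boundary rounding
_BENCHMARK_TRACT_CLASSES = [
    # (count per 200 tracts, min Mb, max Mb)
    (180, 0.30, 0.90),
    (12, 1.15, 1.85),
    (6, 2.15, 2.65),
    (2, 3.60, 4.40),
]


def sweep_benchmark_panel(
    n_individuals: int = 30,
    config: SimConfig | None = None,
    n_tracts: int = 200,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """HWE background panel with implanted homozygous tracts.

    Builds an unrelated-founder panel and implants ``n_tracts`` homozygous
    tracts whose length-class composition is dominated by short (<1 Mb)
    tracts.  Calls are complete (no missingness), matching an imputed WGS
    panel, so window missing-call allowances never bind.  Returns the
    matrix and the implanted-tract table.
    """
    if config is None:
        config = SimConfig(missing_rate=0.0)
    ped = Pedigree()
    for i in range(n_individuals):
        ped.add_founder(f"S{i + 1}")
    matrix, _ = simulate_panel(ped, config)
    rng = np.random.default_rng(config.seed + 7)

    lengths = []
    for count, lo, hi in _BENCHMARK_TRACT_CLASSES:
        k = int(round(count * n_tracts / 200))
        lengths.extend(rng.uniform(lo * 1e6, hi * 1e6, size=k))
    rng.shuffle(lengths)

    rows = []
    cursors = {}  # (individual, chrom) -> next free bp
    order = [(i, c) for i in range(n_individuals) for c in config.chromosomes]
    for length in lengths:
        rng.shuffle(order)
        for i, chrom in order:
            # leave >= 0.5 Mb of heterozygous background between tracts
            start = cursors.get((i, chrom), 1) + int(rng.integers(500_000, 1_500_000))
            end = start + int(length) - 1
            if end <= config.chrom_length - 500_000:
                rows.append(
                    {
                        "individual": matrix.samples[i],
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                    }
                )
                cursors[(i, chrom)] = end
                break
        else:
            raise ValueError("genome too small for the requested tract count")
    tracts = pd.DataFrame(rows, columns=["individual", "chrom", "start", "end"])
    return implant_tracts(matrix, tracts), tracts


# ---------------------------------------------------------------------------
# Stock pedigrees for estimator-recovery experiments


def full_sib_pedigree(n_pairs: int = 25, n_offspring_per_pair: int = 2) -> Pedigree:
    """Independent founder pairs -> full-sib pairs -> inbred offspring (F=0.25).

    Each founder pair produces two full sibs whose matings yield
    ``n_offspring_per_pair`` offspring named ``FSO*``.
    """
    ped = Pedigree()
    for i in range(n_pairs):
        p1 = ped.add_founder(f"P{2 * i + 1}")
        p2 = ped.add_founder(f"P{2 * i + 2}")
        a = ped.add_offspring(f"A{i + 1}", p1, p2)
        b = ped.add_offspring(f"B{i + 1}", p1, p2)
        for k in range(n_offspring_per_pair):
            ped.add_offspring(f"FSO{i + 1}_{k + 1}", a, b)
    return ped


def mixed_pedigree() -> Pedigree:
    """A 60-individual pedigree mixing four expected-inbreeding classes.

    20 founders; 5 full-sib pairs and 5 half-sib pairs in G1 (all F=0);
    G2 holds 10 full-sib offspring (F=0.25) and 5 half-sib offspring
    (F=0.125); G3 holds 5 offspring of two full-sib offspring (F=0.375).
    """
    ped = Pedigree()
    P = [ped.add_founder(f"P{i + 1}") for i in range(20)]
    A, B, C, Cp = [], [], [], []
    for i in range(5):
        A.append(ped.add_offspring(f"A{i + 1}", P[2 * i], P[2 * i + 1]))
        B.append(ped.add_offspring(f"B{i + 1}", P[2 * i], P[2 * i + 1]))
    for i in range(5):
        sire = P[10 + i]
        C.append(ped.add_offspring(f"C{i + 1}", sire, P[15 + i]))
        Cp.append(ped.add_offspring(f"D{i + 1}", sire, P[15 + (i + 1) % 5]))
    FSO, FSOp = [], []
    for i in range(5):
        FSO.append(ped.add_offspring(f"FSO{i + 1}", A[i], B[i]))
        FSOp.append(ped.add_offspring(f"FSX{i + 1}", A[i], B[i]))
    for i in range(5):
        ped.add_offspring(f"HSO{i + 1}", C[i], Cp[i])
    for i in range(5):
        ped.add_offspring(f"DBL{i + 1}", FSO[i], FSOp[i])
    return ped
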