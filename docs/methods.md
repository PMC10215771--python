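# Methods

`rohkit` analyses diploid biallelic SNP panels for runs of homozygosity
(ROH), genomic inbreeding and ROH-island selection signatures, and ships a
pedigree gene-dropping simulator that provides ground truth for every
stage. This note documents the models, the parameters that matter, the
numerical choices, and what the simulator does and does not emulate.

## Genotype model and quality control

Genotypes are codes 0/1/2 (alt-allele dosage) with a missing sentinel,
held as an individuals × sites `int8` matrix; coordinates are 1-based
inclusive throughout, and chromosomes keep their input order (positions
sorted within chromosomes). QC applies, in order:

1. individual call rate ≥ `indiv_call_min` (default 0.9), computed on the
   raw panel — individuals are filtered before sites because a call rate
   is only meaningful on the unfiltered site set;
2. site quality ≥ `qual_min` (default 30), only where QUAL is present;
3. site missing rate ≤ `site_missing_max` (default 0.1), on the remaining
   individuals;
4. minor allele frequency ≥ `maf_min` (default 0.05), with non-missing
   alleles only in the denominator.

All thresholds are inclusive; a site at MAF exactly 0.05 survives.
Half-calls (`./1`) are treated as missing; haploid GT entries are an
error. The filter is idempotent by construction.

## Diversity statistics

Per site with alt frequency *p* and *n* non-missing diploid calls:
H<sub>O</sub> = het/*n*; H<sub>E</sub> = 2*p*(1−*p*) (sample frequency,
no small-sample correction — the PLINK convention); MAF = min(*p*, 1−*p*);
π = 2*p*(1−*p*)·2*n*/(2*n*−1), the unbiased per-site nucleotide diversity
(the VCFtools definition). π and H<sub>E</sub> therefore agree site-wise up
to the 2*n*/(2*n*−1) factor — an identity the tests assert. Reported
"±" values are standard deviations over sites. P<sub>N</sub> is the
fraction of sites with MAF > 0.

LD decay is the squared Pearson correlation of genotype dosages over
individuals with both calls present (the Rogers–Huff composite estimator
for unphased data, as implemented by PopLDdecay), pooled into equal-width
distance bins (defaults: 300 kb span, 100 bins). Pairs involving a
zero-variance site are skipped and counted, not imputed.

## ROH detection

The caller reproduces the PLINK v1.9 `--homozyg` sliding-window scheme: a
window of `window_snps` (default 50) consecutive SNPs slides one SNP at a
time; a window is homozygous iff it has ≤ `window_max_het` (default 1)
heterozygous and ≤ `window_max_missing` (default 5) missing calls; a SNP
is in-run iff the homozygous fraction of windows covering it is ≥
`hit_threshold` (default 0.05). Maximal in-run stretches are split where
the gap between adjacent SNPs exceeds `max_gap` (default 1 Mb) and kept
iff they span ≥ `min_snps` (default 50) SNPs, ≥ `min_length` (default
100 kb), and ≤ `min_density` (default 50 kb/SNP). The het/missing
allowances apply per *window*, PLINK's semantics, which resolves the
common ambiguity of "one heterozygote allowed per ROH". `min_snps` is
inclusive (≥ 50); a strict reading ("more than 50") would shift results
by at most the single-SNP boundary cases.

Segment coordinates are the first and last member SNP, so length =
end − start + 1; this convention matters at the 100 kb boundary and is
stated in every output header. Length classes are half-open and
lower-inclusive: [0,1), [1,2), [2,3), [3,∞) Mb — a segment of exactly
1 Mb is "1–2 Mb". The class summary reports both the share of segment
*count* and the share of cumulative ROH *length* per class under separate
names, because a single "coverage" column is ambiguous between the two.
Per-chromosome coverage is Σ segment lengths / (chromosome length ×
number of individuals).

A brute-force window-enumeration caller lives in the test suite and is
held to exact set equality with the vectorised implementation on hundreds
of randomized instances.

## Inbreeding coefficients

* **F_ROH** = Σ L<sub>ROH</sub> / L<sub>auto</sub>, decomposed by length
  class; the total is computed as the sum of the class components so the
  additivity identity is exact in floating point. L<sub>auto</sub> is
  either a fixed constant (900 Mb, the conventional chicken autosome
  total) or the sum of the supplied chromosome lengths; both policies are
  exposed because published cohort summaries are not always consistent
  about which denominator was used.
* **F_HOM** = (O − E)/(L − E) per individual over its non-missing sites,
  with E = Σ [1 − 2p(1−p)·2n/(2n−1)] (the PLINK `--het` convention); may
  be negative.
* **F_GRM** = G<sub>jj</sub> − 1 from the VanRaden method-1 genomic
  relationship matrix G = ZZ′ / (2 Σ p<sub>i</sub>(1−p<sub>i</sub>)),
  centred dosages, missing values mean-imputed to 2p (zero after
  centring). GCTA's `--ibc` offers two further diagonal estimators
  (weighted and correlation-based); only the plain VanRaden diagonal is
  implemented here, so small numeric differences from GCTA's alternative
  columns are expected. Allele frequencies are always in-sample.

Under Hardy–Weinberg equilibrium both F_HOM and F_GRM are centred near
zero; with in-sample frequencies the mean F_GRM carries a small negative
O(1/N) bias, visible in the acceptance output (≈ −0.02 at N = 200).

## ROH islands

Per-SNP incidence counts the individuals whose ROH covers the SNP
(interval-indexed, verified against a naive double loop). The island
threshold is the empirical top-1% order statistic (lower quantile); ties
at the threshold are all included, so the selection can slightly exceed
the nominal fraction. If every SNP has the same incidence the threshold
is degenerate: a warning is emitted and everything is selected. Selected
SNPs within `max_gap` = 500 kb on one chromosome merge into an island;
islands with fewer than `min_snps` = 2 SNPs are dropped. Both merge
parameters are exposed — no published consensus exists for them. Genes
(BED, 0-based half-open, converted; or GFF3, native 1-based) annotate an
island on ≥ 1 bp overlap. Functional enrichment is out of scope: it
depends on live external databases.

## The simulator

`simulate` drops founder haplotypes through an explicit pedigree:
founder alt-allele frequencies ~ U(0.05, 0.5); founder haplotypes drawn
independently per site (linkage equilibrium); crossovers per chromosome ~
Poisson(map length), breakpoints uniform, no interference and no obligate
chiasma; genotyping errors flip a call to a uniformly chosen different
code; missingness is applied last. Each chromosome copy carries an
ancestral label, so true autozygous segments (both labels identical) and
the realized autozygous fraction are known exactly; pedigree F comes from
the recursive (tabular) kinship.

Defaults: 2 chromosomes × 20 Mb, 4 000 SNPs per chromosome (1 SNP/5 kb),
3 cM/Mb (a chicken-like genome-wide average), error rate 10⁻³, missing
rate 0.02. These keep a 60-individual cohort under a second on one CPU.

What the simulator does **not** emulate: ancestral LD (founders are in
linkage equilibrium, unlike any real chicken population), mutation,
demographic history, and sex chromosomes. Passing recovery tests
therefore show that the estimators recover *pedigree-scale* autozygosity
from marker data; they do not validate behaviour on deep
coalescent-scale haplotype sharing.

### Experiment design choices

* **Recovery experiments** (full-sib mean F_ROH, correlation of F_ROH
  with pedigree F) use 6 chromosomes × 20 Mb at the default density. On a
  40 Mb genome the Mendelian-sampling standard deviation of realized
  inbreeding (~0.1 for a full-sib loop) would swamp the spread between
  pedigree classes; 120 Mb across six independently segregating
  chromosomes brings the within-class variance well below the
  between-class variance (~0.017). The mixed recovery pedigree has 60
  individuals in four expected-F classes (0, 0.125, 0.25, 0.375); the
  full-sib experiment uses 50 inbred offspring from 25 independent founder
  pairs so the Monte-Carlo standard error of the class mean (~0.03) is
  small against the ±0.05 acceptance band.
* **Window-size sweep benchmark** (`sweep_benchmark_panel`): a
  Hardy–Weinberg background panel with 200 implanted homozygous tracts,
  90% of them < 1 Mb — the composition seen in livestock WGS cohorts,
  which pedigree gene dropping cannot produce at test scale (it would
  need hundreds of simulated generations). Calls are complete, matching
  an imputed WGS panel, so the window missing-call allowance never binds;
  tract lengths are sampled ≥ 0.1 Mb away from every class boundary so
  the sweep measures detection behaviour rather than boundary rounding.
  On this benchmark the < 1 Mb count falls monotonically as the window
  grows from 50 to 200 SNPs (a tract shorter than one window admits no
  fully interior window and disappears) while the > 3 Mb count is
  unchanged.
* **Island sweep fixture**: one 1 Mb locus forced homozygous in 80% of
  individuals over ~5% background autozygosity; the top-1% scan must
  return exactly one island containing the locus.

## Numerical details and degenerate inputs

Threshold comparisons on exact fractions (MAF, missing rate) use a 1e-9
guard so integer-ratio boundaries are decided as written. Sites with zero
non-missing calls are excluded from diversity summaries and counted.
r² pairs with < 2 shared calls or zero variance are skipped. A GRM on a
panel containing monomorphic sites is an error (QC removes them). An
individual with no ROH has F_ROH = 0; an empty segment list yields a
zero summary table, not an error. All simulation randomness derives from
one seed via spawned generator streams; identical configs give
byte-identical outputs.

## Problem sizes

Test-suite and acceptance-script experiments use 40–120 Mb genomes with
7 600–24 000 SNPs and 40–200 individuals; the full suite runs in a few
seconds on one CPU. These scales were chosen so Monte-Carlo error is
controlled by design (see above), with every tolerance fixed before the
corresponding experiment was run.
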