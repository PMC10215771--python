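"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain enumeration loops, deliberately sharing
no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def hit_fractions_bruteforce(calls, window_snps, max_het, max_missing):
    """Per-SNP homozygous-window fraction by enumerating every window."""
    calls = list(calls)
    S = len(calls)
    n_hit = [0] * S
    n_win = [0] * S
    for k in range(0, S - window_snps + 1):
        window = calls[k : k + window_snps]
        ok = (
            sum(1 for c in window if c == 1) <= max_het
            and sum(1 for c in window if c == MISSING) <= max_missing
        )
        for i in range(k, k + window_snps):
            n_win[i] += 1
            if ok:
                n_hit[i] += 1
    return [h / w if w else 0.0 for h, w in zip(n_hit, n_win)]


def call_roh_bruteforce(calls, pos, params):
    """Segments (start, end, n_snps) for one individual on one chromosome.

    Re-applies the published rules step by step: threshold the enumerated
    hit fractions, cut runs at large gaps, then filter on SNP count,
    length and density.
    """
    frac = hit_fractions_bruteforce(
        calls, params.window_snps, params.window_max_het, params.window_max_missing
    )
    in_run = [f >= params.hit_threshold for f in frac]
    segments = []
    run: list[int] = []
    for i, flag in enumerate(in_run):
        if flag:
            if run and pos[i] - pos[run[-1]] > params.max_gap:
                segments.extend(_finish(run, pos, params))
                run = []
            run.append(i)
        else:
            if run:
                segments.extend(_finish(run, pos, params))
            run = []
    if run:
        segments.extend(_finish(run, pos, params))
    return segments


def _finish(run, pos, params):
    n = len(run)
    start, end = pos[run[0]], pos[run[-1]]
    length = end - start + 1
    if (
        n >= params.min_snps
        and length >= params.min_length
        and length / n <= params.min_density
    ):
        return [(int(start), int(end), n)]
    return []


def pearson_r2_bruteforce(x, y):
    """Squared Pearson correlation with pairwise deletion of missing calls."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return None
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def qc_site_keep_bruteforce(column, quals_i, n_samples, params):
    """Evaluate each site-level QC criterion directly for one site column."""
    obs = [c for c in column if c != MISSING]
    if quals_i is not None and not np.isnan(quals_i) and quals_i < params.qual_min:
        return False
    if (len(column) - len(obs)) / len(column) > params.site_missing_max + 1e-12:
        return False
    if not obs:
        return False
    an = 2 * len(obs)
    ac = sum(obs)
    maf = min(ac, an - ac) / an
    return maf >= params.maf_min - 1e-12


def incidence_bruteforce(segments, chroms, pos, individuals):
    """Naive per-SNP, per-individual, per-segment containment count."""
    counts = []
    for c, p in zip(chroms, pos):
        n = 0
        for ind in individuals:
            covered = any(
                s.individual == ind and s.chrom == c and s.start <= p <= s.end
                for s in segments
            )
            n += covered
        counts.append(n)
    return counts


def overlap_bruteforce(islands, genes):
    """Exhaustive island x gene 1-based-inclusive overlap test."""
    out = []
    for isl in islands:
        hits = sorted(
            {
                str(g.gene)
                for g in genes.itertuples(index=False)
                if str(g.chrom) == isl.chrom
                and g.start <= isl.end
                and g.end >= isl.start
            }
        )
        out.append(hits)
    return out
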