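import numpy as np
import pandas as pd
import pytest

import rohkit as rk

#: genome used for estimator-recovery experiments: same marker density as
#: the default (1 SNP / 5 kb) but six chromosomes, so the Mendelian-sampling
#: variance of realized inbreeding stays small next to the pedigree spread
RECOVERY_CONFIG = dict(n_chrom=6, chrom_length=20_000_000, n_sites=4_000)


def make_matrix(calls, positions=None, chroms=None, quals=None):
    """Build a GenotypeMatrix from a (n_individuals x n_sites) code array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10_000
    if chroms is None:
        chroms = ["1"] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": np.full(n_sites, np.nan, dtype=np.float32)
            if quals is None
            else np.asarray(quals, dtype=np.float32),
        }
    )
    return rk.GenotypeMatrix([f"ind{i}" for i in range(n_ind)], sites, calls)


@pytest.fixture(scope="session")
def mixed_cohort():
    """QC'd mixed-pedigree cohort with truth, used across estimator tests."""
    ped = rk.mixed_pedigree()
    cfg = rk.SimConfig(seed=1, **RECOVERY_CONFIG)
    matrix, truth = rk.simulate_panel(ped, cfg)
    chrom_lengths = {c: cfg.chrom_length for c in cfg.chromosomes}
    matrix, _ = rk.qc_filter(matrix)
    segments = rk.call_roh(matrix, chrom_lengths)
    return {
        "pedigree": ped,
        "config": cfg,
        "matrix": matrix,
        "truth": truth,
        "segments": segments,
        "chrom_lengths": chrom_lengths,
        "f_ped": ped.inbreeding_table(),
    }


@pytest.fixture(scope="session")
def hwe_panel():
    """200 unrelated founders: genotypes at exact Hardy-Weinberg equilibrium."""
    ped = rk.Pedigree()
    for i in range(200):
        ped.add_founder(f"F{i + 1}")
    cfg = rk.SimConfig(seed=7)
    matrix, _ = rk.simulate_panel(ped, cfg)
    matrix, _ = rk.qc_filter(matrix)
    return matrix
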