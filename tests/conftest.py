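import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from microgwas import GenotypeMatrix, SimulationConfig, simulate_covariates, simulate_genotypes


def make_genotypes(values, chroms=None, positions=None, ids=None):
    """Small hand-built GenotypeMatrix helper (rows = individuals)."""
    values = np.asarray(values, dtype=np.int8)
    n_ind, n_snp = values.shape
    chroms = chroms or ["1"] * n_snp
    positions = positions or list(range(100, 100 + 10 * n_snp, 10))
    ids = ids or [f"s{j}" for j in range(n_snp)]
    meta = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(values, meta, [f"i{i}" for i in range(n_ind)])


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 60-individual, 200-SNP simulated cohort."""
    cfg = SimulationConfig(
        n_individuals=60, n_snps=200, n_taxa=20, n_causal_pairs=2, seed=11
    )
    geno, pops = simulate_genotypes(cfg)
    cov = simulate_covariates(pops, cfg)
    return cfg, geno, pops, cov
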