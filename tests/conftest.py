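import numpy as np
import pandas as pd
import pytest

from bulkseg import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genome():
    """Two short chromosomes, causal locus mid-chr1."""
    return simulate.GenomeModel(
        chrom_lengths={"chr1": 1_000_000, "chr2": 800_000},
        markers={
            "chr1": np.arange(50_000, 1_000_001, 50_000, dtype=np.int64),
            "chr2": np.arange(50_000, 800_001, 50_000, dtype=np.int64),
        },
        rate_cm_per_mb=2.0,
        causal=("chr1", 500_000),
    )


@pytest.fixture
def two_marker_genome():
    """Single chromosome whose two markers sit 50 cM apart (25 Mb at 2 cM/Mb)."""
    return simulate.GenomeModel(
        chrom_lengths={"chr1": 26_000_000},
        markers={"chr1": np.array([1_000_000, 26_000_000], dtype=np.int64)},
        rate_cm_per_mb=2.0,
        causal=("chr1", 1_000_000),
    )


@pytest.fixture
def snp_table():
    """Ten hand-enumerable SNP records for filter tests."""
    return pd.DataFrame(
        {
            "chrom": ["A01"] * 10,
            "pos": np.arange(1, 11) * 1000,
            "ref": ["A"] * 9 + ["A"],
            "alt": ["G"] * 8 + ["A", "G"],  # row 9 monomorphic
            "M_tall": [50, 0, 5, 120, 30, 90, 60, 40, 30, 30],
            "P_tall": [10, 0, 2, 100, 20, 30, 0, 10, 30, 20],
            "M_dwarf": [55, 40, 50, 60, 5, 80, 70, 300, 40, 45],
            "P_dwarf": [5, 20, 10, 40, 1, 20, 2, 20, 20, 15],
            "missing": [False] * 9 + [True],  # row 10 flagged missing
        }
    )


@pytest.fixture
def counts_3v3(rng):
    """Small Poisson count matrix with labelled groups."""
    lam = rng.lognormal(3.5, 1.0, 300)
    cols = ["Tall1", "Tall2", "Tall3", "Dwarf1", "Dwarf2", "Dwarf3"]
    counts = pd.DataFrame(
        rng.poisson(lam[:, None], (300, 6)),
        index=pd.Index([f"g{i}" for i in range(300)], name="gene_id"),
        columns=cols,
    )
    groups = pd.Series(["tall"] * 3 + ["dwarf"] * 3, index=cols)
    return counts, groups
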