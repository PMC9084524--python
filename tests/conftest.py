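import numpy as np
import pandas as pd
import pytest

from placentakit.motif_metrics import KmerZscoreTable, RNA_BASES


def random_kmer_table(rng: np.random.Generator, n_rows: int) -> KmerZscoreTable:
    """Random 7-mer Z-score table with unique k-mers; Z may be negative."""
    kmers = set()
    while len(kmers) < n_rows:
        kmers.add("".join(rng.choice(list(RNA_BASES), size=7)))
    kmers = sorted(kmers)
    z = rng.normal(2.0, 3.0, size=len(kmers))
    return KmerZscoreTable(pd.Series(z, index=kmers))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def single_litter_frame():
    """One litter, 3 WT at the bottom ranks and 3 KO at the top."""
    return pd.DataFrame(
        {
            "litter_id": ["L1"] * 6,
            "specimen_id": [f"p{i}" for i in range(6)],
            "tissue": ["placenta"] * 6,
            "weight": [0.08, 0.09, 0.10, 0.11, 0.12, 0.13],
            "effective_genotype": ["WT", "WT", "WT", "KO", "KO", "KO"],
        }
    )
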