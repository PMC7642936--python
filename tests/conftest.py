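import numpy as np
import pandas as pd
import pytest

from corediv import SimParams, simulate
from corediv.genotype_io import BaseMatrix, encode_seq


def make_base_matrix(seqs: dict[str, str], chrom: str = "A01") -> BaseMatrix:
    """Hand fixture helper: equal-length ACGT- strings -> BaseMatrix with
    loci at 1 Mb spacing on one chromosome."""
    width = len(next(iter(seqs.values())))
    loci = pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(width)],
            "chrom": [chrom] * width,
            "pos": [(i + 1) * 1_000_000 for i in range(width)],
        }
    )
    return BaseMatrix(
        list(seqs), loci, np.vstack([encode_seq(s) for s in seqs.values()])
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition synthetic collection."""
    return simulate(SimParams(seed=0))


@pytest.fixture(scope="session")
def small_sim():
    """A compact collection for fast I/O round-trip tests."""
    return simulate(
        SimParams(
            n_chromosomes=2,
            markers_per_chrom=10,
            n_clades=2,
            n_accessions_per_clade=5,
            replicate_design={2: 3},
            seed=11,
        )
    )
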