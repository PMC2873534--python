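import numpy as np
import pandas as pd
import pytest

from cnapeel import ArmTable, CopyNumberMatrix, GeneTable, MarkerGrid


@pytest.fixture
def small_grid():
    """Ten markers on one chromosome, 1 kb apart."""
    return MarkerGrid(
        names=np.array([f"m{i}" for i in range(10)], dtype=object),
        chrom=np.array(["1"] * 10, dtype=object),
        pos=np.arange(1, 10_001, 1_000, dtype=np.int64),
    )


@pytest.fixture
def two_chrom_grid():
    """Ten markers each on chromosomes 1 and 2."""
    return MarkerGrid(
        names=np.array([f"m{i}" for i in range(20)], dtype=object),
        chrom=np.array(["1"] * 10 + ["2"] * 10, dtype=object),
        pos=np.tile(np.arange(1, 10_001, 1_000, dtype=np.int64), 2),
    )


@pytest.fixture
def two_chrom_arms():
    return ArmTable(records=pd.DataFrame(
        [("1", "p", 1, 4500), ("1", "q", 4501, 10_000),
         ("2", "p", 1, 4500), ("2", "q", 4501, 10_000)],
        columns=["chrom", "arm", "start", "end"],
    ))


def make_matrix(values, grid, samples=None):
    values = np.asarray(values, dtype=float)
    if samples is None:
        samples = tuple(f"S{j}" for j in range(values.shape[1]))
    return CopyNumberMatrix(values=values, grid=grid, samples=samples)


@pytest.fixture
def gene_table():
    return GeneTable(records=pd.DataFrame(
        [("GENE_A", "1", 2000, 3000), ("GENE_B", "1", 8000, 9500),
         ("GENE_C", "2", 100, 5000)],
        columns=["symbol", "chrom", "start", "end"],
    ))
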