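import numpy as np
import pytest

from lascout.data_model import ExpressionDataset, SeriesTable
from lascout.preprocess import transform_dataset
from lascout.synthetic_data import MediationFn, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_series(rng):
    """Two series sharing 5 of 8 genes, 2 samples each."""
    genes_a = [f"SO{i:04d}" for i in range(8)]
    genes_b = genes_a[:5] + ["SO9001", "SO9002"]
    a = SeriesTable("GSA", genes_a, ["s1", "s2"], rng.standard_normal((8, 2)))
    b = SeriesTable("GSB", genes_b, ["t1", "t2"], rng.standard_normal((7, 2)))
    return a, b


@pytest.fixture
def random_dataset(rng):
    """25 genes x 20 samples over two batches, no planted structure, 10% missing."""
    values = rng.standard_normal((25, 20))
    values[rng.random(values.shape) < 0.10] = np.nan
    return ExpressionDataset(
        gene_ids=[f"G{i:03d}" for i in range(25)],
        sample_ids=[f"s{j:02d}" for j in range(20)],
        batch_labels=["B1"] * 12 + ["B2"] * 8,
        values=values,
    )


@pytest.fixture
def planted_dataset():
    """Batched synthetic dataset with one strong planted mediation triplet."""
    spec = SyntheticSpec(
        n_genes=40,
        batch_sizes=(20, 60, 8),
        planted_triplets=((0, 1, 2, MediationFn("tanh", 0.9, 1.0)),),
        seed=11,
    )
    ds, truth = generate_dataset(spec)
    return ds, truth


@pytest.fixture
def planted_transformed(planted_dataset):
    ds, truth = planted_dataset
    return transform_dataset(ds), truth
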