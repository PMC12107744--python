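import numpy as np
import pytest

from dracoon.data_io import CandidateEdgeSet, ExpressionDataset


@pytest.fixture
def small_dataset():
    """4 genes x 8 samples, 4 A + 4 B, deterministic values."""
    rng = np.random.default_rng(0)
    values = rng.normal(5.0, 1.0, size=(4, 8))
    cond = {f"s{j}": ("A" if j < 4 else "B") for j in range(8)}
    with pytest.warns(UserWarning):  # < 10 samples per condition
        ds = ExpressionDataset(
            gene_ids=[f"g{i}" for i in range(4)],
            sample_ids=[f"s{j}" for j in range(8)],
            values=values,
            condition_of=cond,
        )
    return ds


@pytest.fixture
def labeled_dataset():
    """20 genes x 40 samples (20 A + 20 B), i.i.d. null data."""
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(20)]
    samples = [f"s{j:02d}" for j in range(40)]
    cond = {s: ("A" if j < 20 else "B") for j, s in enumerate(samples)}
    return ExpressionDataset(
        gene_ids=genes,
        sample_ids=samples,
        values=rng.normal(6.0, 1.0, size=(20, 40)),
        condition_of=cond,
    )


@pytest.fixture
def single_pair_candidates(labeled_dataset):
    return CandidateEdgeSet(mode=2, edges=[("g00", "g01")], directed=True)
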