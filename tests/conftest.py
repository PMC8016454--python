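import pytest

from dmsimpact.datasets import DmsDataset, VariantRecord
from dmsimpact.synthetic import SyntheticSpec, generate_corpus


def make_dataset(scores, wt_score=None, dataset_id="d1", protein_id="P1", start=1):
    """Build a small single-position-per-record dataset from raw scores.

    Each score becomes an A->V missense record at consecutive positions,
    which is enough structure for normalization tests.
    """
    records = [
        VariantRecord(
            protein_id=protein_id, position=start + i, wt="A", var="V", score=s
        )
        for i, s in enumerate(scores)
    ]
    return DmsDataset(
        dataset_id=dataset_id,
        protein_id=protein_id,
        records=records,
        wt_score=wt_score,
    )


@pytest.fixture(scope="session")
def corpus():
    """Default synthetic corpus (noisy, rank-normalized path exercised)."""
    return generate_corpus(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def zero_noise_corpus():
    """Noise-free corpus for exact-recovery identities."""
    return generate_corpus(SyntheticSpec(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_corpus():
    """A fast three-protein corpus for end-to-end and CLI tests."""
    return generate_corpus(
        SyntheticSpec(seed=3, n_proteins=3, protein_length=25, homolog_depth=15)
    )
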