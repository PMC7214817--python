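import numpy as np
import pytest

from crypticpts.sequence_io import GeneLocus
from crypticpts.synthetic_data import SimConfig, generate_locus


@pytest.fixture
def default_config():
    return SimConfig(seed=11)


@pytest.fixture
def pgd1_like_locus(default_config):
    """Synthetic locus with the published pgd1 geometry planted."""
    locus, _ = generate_locus(default_config)
    return locus


@pytest.fixture
def pgd1_like_truth(default_config):
    _, truth = generate_locus(default_config)
    return truth


def make_locus(upstream: str, cds: str = "ATGGCTGCTTAA", gene_id: str = "g") -> GeneLocus:
    return GeneLocus(gene_id=gene_id, upstream_seq=upstream, cds_seq=cds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
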