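import numpy as np
import pytest
from hypothesis import settings

from smoketc.io_formats import CountMatrix, SampleRecord

settings.register_profile("ci", derandomize=True, database=None, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def two_group_matrix(
    rng,
    n_genes=200,
    n_per_group=5,
    phi=0.1,
    mean_log=4.0,
    sd_log=1.0,
    time_label="9mo",
):
    """Null NB count matrix: AC vs CS at one time point."""
    mu = np.exp(rng.normal(mean_log, sd_log, n_genes))
    n = 2 * n_per_group
    if phi > 0:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (n_genes, n))
    else:
        counts = rng.poisson(np.broadcast_to(mu[:, None], (n_genes, n)))
    samples = [
        SampleRecord(f"s{i}", "AC" if i < n_per_group else "CS", time_label)
        for i in range(n)
    ]
    return CountMatrix(
        gene_ids=[f"g{i:04d}" for i in range(n_genes)],
        samples=samples,
        counts=counts.astype(np.int64),
    )


@pytest.fixture
def null_matrix(rng):
    return two_group_matrix(rng)
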