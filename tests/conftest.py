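import numpy as np
import pytest

from cacao_popgen.core_io import MISSING, GenotypeMatrix, VariantSite


def make_matrix(calls, positions=None, chrom="chr1", pop_of=None, samples=None):
    """Build a GenotypeMatrix from a (samples x sites) array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    sites = [VariantSite(chrom, int(p)) for p in positions]
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls,
                          pop_of=pop_of or {})


def random_matrix(rng, n_samples=20, n_sites=200, missing_rate=0.0,
                  pop_split=None):
    """Random genotype matrix with optional missing calls and two populations."""
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    pop_of = {}
    if pop_split is not None:
        for i in range(n_samples):
            pop_of[f"s{i}"] = "A" if i < pop_split else "B"
    return make_matrix(calls, positions=np.arange(1, n_sites + 1) * 7,
                       pop_of=pop_of)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
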