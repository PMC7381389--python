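import numpy as np
import pytest

from introscan.io import MISSING, GenotypeMatrix

M = MISSING


def make_matrix(calls, chrom="A01", positions=None, samples=None):
    """Build a GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n_sites, n_samples = calls.shape
    if positions is None:
        positions = list(range(1, n_sites + 1))
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if isinstance(chrom, str):
        chrom = [chrom] * n_sites
    return GenotypeMatrix(
        chrom=chrom,
        pos=positions,
        ref=["A"] * n_sites,
        alt=["G"] * n_sites,
        samples=samples,
        calls=calls,
    )


def random_matrix(rng, n_sites, n_samples, missing_rate=0.1, chrom="A01",
                  max_pos=None):
    """Random genotype matrix with uniform call codes and missingness."""
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = M
    if max_pos is None:
        max_pos = max(10 * n_sites, n_sites + 1)
    positions = np.sort(rng.choice(np.arange(1, max_pos + 1), size=n_sites,
                                   replace=False))
    return make_matrix(calls, chrom=chrom, positions=positions)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
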