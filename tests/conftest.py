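import numpy as np
import pytest

from prstuning.io import SummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stats(z, f0=None, f1=None, n0=200, n1=200, chrom=None, pos=None,
               a1=None, a2=None, p_value=None):
    """Small SummaryStats builder with sensible fill-ins."""
    z = np.asarray(z, dtype=float)
    M = z.size
    if f0 is None:
        f0 = np.full(M, 0.5)
    if f1 is None:
        f1 = np.asarray(f0, dtype=float).copy()
    return SummaryStats(
        snp_id=np.array([f"rs{i}" for i in range(M)], dtype=object),
        z=z, n0=n0, n1=n1,
        chrom=np.repeat("1", M) if chrom is None else chrom,
        pos=np.arange(1, M + 1, dtype=float) if pos is None else pos,
        a1=a1, a2=a2, f0_hat=np.asarray(f0, float), f1_hat=np.asarray(f1, float),
        p_value=p_value)


@pytest.fixture
def small_stats():
    rng = np.random.default_rng(7)
    M = 40
    f = rng.uniform(0.1, 0.9, M)
    return make_stats(rng.standard_normal(M), f0=f, f1=f)
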