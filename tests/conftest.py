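import numpy as np
import pytest
from hypothesis import settings

from sweepwatch.hapio import HaplotypeMatrix, VariantSite

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def make_matrix(rows, positions=None, chrom="chr1", ids=None):
    """Build a HaplotypeMatrix from a list of 0/1 strings or an array."""
    data = np.array(
        [[int(c) for c in r] for r in rows] if isinstance(rows[0], str)
        else rows,
        dtype=np.uint8,
    )
    m = data.shape[1]
    if positions is None:
        positions = [100 * (j + 1) for j in range(m)]
    sites = [VariantSite(chrom, int(p), "A", "T") for p in positions]
    if ids is None:
        ids = [f"S{i // 2 + 1:03d}_{'AB'[i % 2]}" for i in range(data.shape[0])]
    return HaplotypeMatrix(sites, data, ids)


def random_matrix(rng, n_chrom, n_sites, chrom="chr1"):
    data = rng.integers(0, 2, size=(n_chrom, n_sites), dtype=np.uint8)
    positions = np.sort(
        rng.choice(np.arange(1, 100 * n_sites + 1), size=n_sites, replace=False)
    )
    return make_matrix(data, positions=positions, chrom=chrom,
                       ids=[f"c{i}" for i in range(n_chrom)])


@pytest.fixture(scope="session")
def small_sweep_dataset(tmp_path_factory):
    """One small simulated recessive dataset shared across tests."""
    import sweepwatch as sw

    out = tmp_path_factory.mktemp("sweepdata")
    params = sw.SweepSimParams(seed=11, n_anc=20, n_der=20, n_sites=200,
                               L=200_000, core_pos=100_000, rG=2e-5)
    return sw.emit_dataset(params, out)
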