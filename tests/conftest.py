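import numpy as np
import pytest

from urocnv import ChromSizes, GenomeBins, tile_genome
from urocnv.simulate import toy_genome


@pytest.fixture(scope="session")
def hg19_bins() -> GenomeBins:
    return tile_genome(ChromSizes.hg19(), 60_000)


@pytest.fixture(scope="session")
def small_bins() -> GenomeBins:
    """Two-chromosome toy tiling with known GC, for fast unit tests."""
    sizes = ChromSizes((("chr1", 600_000), ("chr2", 330_000)), "toy-small")
    bins = tile_genome(sizes, 60_000)
    rng = np.random.default_rng(11)
    bins.gc = rng.uniform(0.3, 0.6, bins.n_bins)
    return bins


@pytest.fixture(scope="session")
def toy_bins() -> GenomeBins:
    """The default 5,000-bin 22-chromosome synthetic genome."""
    return toy_genome(seed=0)


def make_profile(bins, values, usable=None, sample_id="test"):
    from urocnv.normalize import LogRatioProfile

    values = np.asarray(values, dtype=float)
    if usable is None:
        usable = ~np.isnan(values) & ~bins.masked
    lr = np.where(usable, values, np.nan)
    return LogRatioProfile(sample_id, bins, lr, usable)
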