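import numpy as np
import pytest

from regionsig import BinSeries, SignatureCatalog, synthetic_catalog
from regionsig.catalog96 import Bin


@pytest.fixture(scope="session")
def catalog4() -> SignatureCatalog:
    """Four moderately-overlapping synthetic signatures."""
    return synthetic_catalog(4, overlap=0.3)


@pytest.fixture(scope="session")
def catalog2_orthogonal() -> SignatureCatalog:
    """Two signatures with disjoint channel support."""
    return synthetic_catalog(2, overlap=0.0)


def series_from_counts(counts: np.ndarray, mode: str = "genome_wise", bin_size: int = 100,
                       chrom: str = "1", bin_width: int = 1_000_000) -> BinSeries:
    """Build a bin series directly from a B x 96 count matrix (synthetic spans)."""
    counts = np.asarray(counts, dtype=np.int64)
    bins = tuple(
        Bin(
            bin_index=i,
            chrom_start=chrom,
            pos_start=i * bin_width,
            chrom_end=chrom,
            pos_end=(i + 1) * bin_width,
            n_mutations=int(row.sum()),
            counts=row,
        )
        for i, row in enumerate(counts)
    )
    return BinSeries(bins=bins, mode=mode, bin_size=bin_size, sample_id="test")


def random_series(rng: np.random.Generator, n_bins: int, catalog: SignatureCatalog,
                  muts_per_bin: int = 80) -> BinSeries:
    """Bins with counts drawn from random mixtures of the catalog."""
    counts = np.empty((n_bins, 96), dtype=np.int64)
    for i in range(n_bins):
        pi = rng.dirichlet(np.ones(catalog.n_signatures))
        mix = pi @ catalog.emissions
        counts[i] = rng.multinomial(muts_per_bin, mix)
    return series_from_counts(counts)
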