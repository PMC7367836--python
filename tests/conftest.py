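import numpy as np
import pytest

from fragsig import BinnedTrack, GenomeTable
from fragsig.repliseq import RTProfile


def make_track(values_by_chrom: dict[str, list | np.ndarray], bin_size: int) -> BinnedTrack:
    """Build a BinnedTrack whose chromosomes exactly fit the given values."""
    genome = GenomeTable(
        {c: len(v) * bin_size for c, v in values_by_chrom.items()}
    )
    return BinnedTrack(
        genome, bin_size, {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    )


def make_profile(
    values: list | np.ndarray,
    bin_size: int = 5000,
    condition: str = "control",
    replicate: int = 0,
    chrom: str = "chr1",
) -> RTProfile:
    track = make_track({chrom: values}, bin_size)
    return RTProfile(track, f"{condition}_{replicate}", condition, replicate)


@pytest.fixture
def tiny_genome() -> GenomeTable:
    return GenomeTable({"chr1": 100_000, "chr2": 50_000})
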