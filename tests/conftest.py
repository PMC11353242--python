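import numpy as np
import pandas as pd
import pytest

from cinmetrics.genome import GenomeModel, TrueCNProfile
from cinmetrics.cnprofile import BinTrack


@pytest.fixture
def small_genome() -> GenomeModel:
    return GenomeModel(
        names=("chrA", "chrB"),
        lengths=(50_000_000, 30_000_000),
        bin_size=1_000_000,
        ploidy=2,
    )


@pytest.fixture
def neutral_profile(small_genome) -> TrueCNProfile:
    rows = [
        (name, 0, length, small_genome.ploidy)
        for name, length in zip(small_genome.names, small_genome.lengths)
    ]
    return TrueCNProfile(
        segments=pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    )


def make_bin_track(counts, gc=None, chrom="chr1", bin_size=1_000_000) -> BinTrack:
    counts = np.asarray(counts, dtype=float)
    starts = np.arange(len(counts), dtype=np.int64) * bin_size
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + bin_size,
            "gc": np.full(len(counts), 0.45) if gc is None else np.asarray(gc, dtype=float),
            "count": counts,
        }
    )
    return BinTrack(df)
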