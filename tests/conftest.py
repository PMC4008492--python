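import numpy as np
import pandas as pd
import pytest

from cnespacers.tracks import ElementTrack


def make_track(intervals, chrom="chr1", strands=None, sizes=None):
    """Build an ElementTrack from a list of (start, end) pairs."""
    intervals = list(intervals)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [s for s, _ in intervals],
            "end": [e for _, e in intervals],
            "name": ".",
            "strand": strands if strands is not None else ".",
        }
    )
    return ElementTrack(df, chrom_sizes=sizes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, n, span, max_len=50):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return np.column_stack([starts, starts + lengths])
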