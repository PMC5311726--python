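import numpy as np
import pytest

from nucrnai import BinTrack, GenomeLayout, Sample


@pytest.fixture
def layout():
    """Two chromosomes; chrII carries a 500-bp trailing remainder."""
    return GenomeLayout(("chrI", "chrII"), (10_000, 5_500), 1000)


@pytest.fixture
def mb_layout():
    return GenomeLayout(("chrI",), (1_000_000,), 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_track(layout, values, state="raw", **kw):
    return BinTrack(layout=layout, values=np.asarray(values, dtype=float),
                    sample=kw.pop("sample", Sample()), normalization_state=state, **kw)
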