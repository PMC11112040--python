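import numpy as np
import pytest

from cutrunkit.core_io import FragmentSet, GenomicInterval, Peak, PeakSet


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One shared synthetic study for file-level tests."""
    from cutrunkit.pipeline import make_fixture
    return make_fixture(tmp_path_factory.mktemp("study"), seed=7)


def make_frags(intervals, sample_id="s", genome_tag="target"):
    return FragmentSet(sample_id=sample_id, genome_tag=genome_tag,
                       fragments=[GenomicInterval(*iv) for iv in intervals])


def make_peaks(intervals, scores=None, prefix="p"):
    scores = scores if scores is not None else [0.0] * len(intervals)
    return PeakSet(peaks=[Peak(GenomicInterval(*iv), score=s,
                               name=f"{prefix}{i + 1}")
                          for i, (iv, s) in enumerate(zip(intervals, scores))])


def random_intervals(rng, n, chrom="chr1", size=100_000, max_len=2_000):
    out = []
    for _ in range(n):
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, size - length))
        out.append((chrom, start, start + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
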