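import numpy as np
import pytest

from epiprime.pipeline import PipelineConfig, run_pipeline
from epiprime.simulate import SimulationConfig, generate_dataset

from epiprime.intervals import GenomicInterval, PeakSet


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic study (seed 1), shared across test modules."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_report():
    """One full pipeline run on the default simulated study."""
    return run_pipeline(PipelineConfig(seed=1))


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=200):
    """Random interval list for oracle comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
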