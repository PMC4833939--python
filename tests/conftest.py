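import numpy as np
import pytest

import dhsdelta as dd


@pytest.fixture(scope="session")
def small_cfg() -> dd.SimulationConfig:
    """A light configuration for cross-checks that need a full dataset."""
    return dd.SimulationConfig(
        seed=11,
        n_chrom=2,
        chrom_length=3_000_000,
        n_genes=150,
        n_sites=1000,
        frac_open=0.10,
        frac_closed=0.10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg) -> dd.SimulatedDataset:
    return dd.simulate_dataset(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_track(rng, chrom="chr1", n_runs=40, span=5000, max_gap=50):
    """Random sorted non-overlapping runs for oracle comparisons."""
    starts, ends, values = [], [], []
    pos = int(rng.integers(0, 20))
    for _ in range(n_runs):
        pos += int(rng.integers(0, max_gap))
        length = int(rng.integers(1, 60))
        starts.append(pos)
        ends.append(pos + length)
        values.append(float(rng.uniform(0, 5)))
        pos += length
        if pos > span:
            break
    return dd.SignalTrack(
        [(chrom, s, e, v) for s, e, v in zip(starts, ends, values)]
    )
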