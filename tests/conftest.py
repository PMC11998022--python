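import numpy as np
import pytest

from statemap import synthdata as sd
from statemap import preprocess as pp


@pytest.fixture(scope="session")
def branch_sim():
    """Small three-terminal conversion simulation with ground truth."""
    cfg = sd.default_conversion_config(seed=0, n_cells_per_timepoint=200)
    ct, gt = sd.simulate_branching_trajectory(cfg)
    return cfg, ct, gt


@pytest.fixture(scope="session")
def branch_embedding(branch_sim):
    _cfg, ct, _gt = branch_sim
    return pp.standard_embedding(ct)


@pytest.fixture(scope="session")
def peak_sim():
    cfg = sd.SimConfig(seed=3, n_peaks=1200)
    return sd.simulate_peak_experiment(cfg)


def random_peakset(rng, n, max_pos=1_000_000, n_chroms=3, max_len=5_000):
    from statemap import PeakSet
    chrom = np.array([f"chr{c}" for c in rng.integers(1, n_chroms + 1, n)],
                     dtype=object)
    start = rng.integers(0, max_pos, n)
    length = rng.integers(1, max_len, n)
    return PeakSet(chrom, start, start + length)
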