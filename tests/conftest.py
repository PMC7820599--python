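import numpy as np
import pytest

from superchrom import GenomicInterval, SignalPeak, generate_landscape
from superchrom.synthetic_data import LandscapeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + int(rng.integers(1, max_len))
            )
        )
    return out


def mask_union(intervals, chroms, size):
    """Per-base boolean-mask oracle for interval unions."""
    masks = {c: np.zeros(size, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def as_peaks(intervals, signal=(1.0,), mark=""):
    return [SignalPeak(iv, signal, source_mark=mark) for iv in intervals]


@pytest.fixture(scope="session")
def small_config():
    """A reduced landscape for unit tests (full defaults are exercised in the
    acceptance suite)."""
    return LandscapeConfig(
        seed=11,
        n_genes=120,
        chrom_sizes={"chr1": 4_000_000, "chr2": 4_000_000},
        n_distractor_k27ac=10,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_landscape(small_config)
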