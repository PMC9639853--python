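"""Shared fixtures: a hand-workable toy screen and small simulator params."""

import numpy as np
import pandas as pd
import pytest

from pptscreen import CountMatrix, SelectionSimParams

# Five 11-mer inserts with column sums of exactly 1000 everywhere, so
# RPM = count * 1000 and every score below can be verified by hand.
TOY_INSERTS = [
    "TTTTTTTTTTT",  # strong PPT, enriched in both conditions
    "CCCAGTGTGGC",  # G-containing, no 6-nt PPT, enriched (stronger at 5x)
    "GGGGGGGGGGG",  # depleted under both conditions
    "AAAAAAAAAAA",  # depleted but below the 10-read initial gate
    "TTTTTAAAAAT",  # roughly neutral
]

TOY_COUNTS = {
    #              init 1x_a 1x_b 1x_c 5x_a 5x_b 5x_c
    "TTTTTTTTTTT": [10, 300, 200, 250, 400, 500, 450],
    "CCCAGTGTGGC": [20, 100, 150, 120, 300, 280, 260],
    "GGGGGGGGGGG": [500,  5,  10,   5,   0,   5,   0],
    "AAAAAAAAAAA": [5,    0,   0,   0,   0,   0,   0],
    "TTTTTAAAAAT": [465, 595, 640, 625, 300, 215, 290],
}

TOY_POPULATIONS = pd.DataFrame({
    "population": ["init", "1x_a", "1x_b", "1x_c", "5x_a", "5x_b", "5x_c"],
    "condition": ["initial"] + ["sel_1x"] * 3 + ["sel_5x"] * 3,
    "replicate": [0, 1, 2, 3, 1, 2, 3],
})


@pytest.fixture
def toy_count_matrix() -> CountMatrix:
    counts = pd.DataFrame(TOY_COUNTS, index=TOY_POPULATIONS["population"]).T
    counts.index.name = "insert"
    return CountMatrix(counts, TOY_POPULATIONS.copy())


@pytest.fixture
def small_params() -> SelectionSimParams:
    """A screen small enough for per-test simulation."""
    return SelectionSimParams(n_variants=300, depth=20_000, bottleneck=20_000,
                              error_rate=0.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_922)
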