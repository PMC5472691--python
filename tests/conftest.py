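"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hyenabiome.study_data import (
    ReadParams,
    TruthParams,
    default_panel,
    generate_reads,
    generate_truth,
)


@pytest.fixture(scope="session")
def small_panel():
    return default_panel(n_16s=2, n_18s=6, seed=501)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(n_hosts=10, params=TruthParams(n_juveniles=3),
                          seed=11)


@pytest.fixture(scope="session")
def clean_reads(small_truth, small_panel):
    """Noise-free reads: no substitutions, no chimeras."""
    params = ReadParams(depth=120, substitution_rate=0.0, chimera_rate=0.0,
                        amplicons_per_genus=2)
    return generate_reads(small_truth, small_panel, params, seed=21)


@pytest.fixture(scope="session")
def genus_counts_from_truth(small_truth):
    """Integer genus x sample counts taken directly from the truth."""
    counts = small_truth.abundance.round().astype(int)
    return counts


def make_metadata(truth) -> pd.DataFrame:
    return truth.metadata_frame()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
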