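import numpy as np
import pandas as pd
import pytest

from barknarx.io_model import Dataset, SectionMeasurement, TreeRecord
from barknarx.series import build_series, series_to_frame, split_series
from barknarx.synthetic import SyntheticProfile, generate_dataset


def make_tree(tree_id="t1", species="pine", H=20.0, rows=None):
    """Hand-built tree; rows = list of (Hb, DOB, k1, k2)."""
    rows = rows or [
        (0.0, 30.0, 1.2, 1.0),
        (0.5, 29.0, 1.1, 0.9),
        (1.3, 28.0, 1.0, 0.9),
        (2.0, 27.0, 0.9, 0.8),
        (4.0, 24.0, 0.8, 0.7),
        (6.0, 21.0, 0.7, 0.6),
    ]
    sections = tuple(SectionMeasurement(*r) for r in rows)
    return TreeRecord(tree_id=tree_id, species=species, H=H, sections=sections)


@pytest.fixture
def tiny_dataset():
    return Dataset(trees=(make_tree("a"), make_tree("b", H=22.0)), species="pine")


@pytest.fixture(scope="session")
def pine_noisy_gen():
    """Noisy pine sample under the default study conditions (shared, read-only)."""
    prof = SyntheticProfile(species="pine", truth="stat1", noise_sd=0.1)
    return generate_dataset(prof, n_trees=60, seed=42)


@pytest.fixture(scope="session")
def pine_noisy_frame(pine_noisy_gen):
    return series_to_frame(build_series(pine_noisy_gen.dataset))


@pytest.fixture(scope="session")
def pine_noisy_split(pine_noisy_frame):
    return split_series(len(pine_noisy_frame), seed=7)
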