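from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from azmap import AcquisitionConfig, Dataset, SyntheticConfig, build_az, generate_dataset


@pytest.fixture(scope="session")
def square_az():
    """Functional AZ from four synchronous events at the corners of a
    200 nm square centered on the origin."""
    corners = np.array([[-100.0, -100.0], [100.0, -100.0], [100.0, 100.0], [-100.0, 100.0]])
    return build_az(corners, bouton_id="sq")


def make_dataset(rows, config=None, traces=None):
    """Dataset from a list of (bouton_id, x, y, stim_index, frame_offset)."""
    events = pd.DataFrame(
        rows, columns=["bouton_id", "x_nm", "y_nm", "stim_index", "frame_offset"]
    )
    return Dataset(config=config or AcquisitionConfig(), events=events, traces=traces or {})


@pytest.fixture(scope="session")
def small_synthetic():
    """A 40-bouton synthetic dataset with ground truth (shared, read-only)."""
    return generate_dataset(SyntheticConfig(seed=11, n_boutons=40))
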