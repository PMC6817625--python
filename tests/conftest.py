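import numpy as np
import pandas as pd
import pytest

from voxpath.path_model import build_path_spec
from voxpath.synthetic_data import default_calibration, generate_cohort


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def cohort(calibration):
    """One deterministic full cohort at the published group sizes."""
    return generate_cohort(calibration, seed=20_260_905)


@pytest.fixture(scope="session")
def default_spec():
    return build_path_spec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_ratings(scores, **kwargs):
    """RatingMatrix from a plain nested list (raters x targets)."""
    from voxpath.ratings import RatingMatrix

    arr = np.asarray(scores)
    return RatingMatrix(
        rater_ids=tuple(f"r{i}" for i in range(arr.shape[0])),
        target_ids=tuple(f"t{j}" for j in range(arr.shape[1])),
        scores=arr,
        **kwargs,
    )
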