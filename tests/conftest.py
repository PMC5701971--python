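import numpy as np
import pandas as pd
import pytest

from brainpe.groupstats import CohortDesign
from brainpe.maps import VolumeMap
from brainpe.preprocess import Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def affine3mm():
    """3-mm isotropic affine with the world origin at the center of a 12^3 grid."""
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = -(np.array([12, 12, 12]) - 1) / 2.0 * 3.0
    return aff


def make_design(sizes=(6, 6, 6, 6), seed=0) -> CohortDesign:
    rng = np.random.default_rng(seed)
    groups = sum(([g] * n for g, n in zip(("NC", "EMCI", "LMCI", "AD"), sizes)), [])
    n = len(groups)
    return CohortDesign(
        pd.DataFrame(
            {
                "subject_id": [f"s{i:03d}" for i in range(n)],
                "group": groups,
                "age": np.round(rng.normal(73, 6, n), 1),
                "sex": [i % 2 for i in range(n)],
                "mmse": np.round(rng.uniform(20, 30, n), 1),
                "faq": np.round(rng.uniform(0, 20, n), 1),
                "cdr": [0.0 if g == "NC" else 0.5 for g in groups],
            }
        )
    )


@pytest.fixture
def small_design():
    return make_design()


def constant_map(value, shape=(12, 12, 12), affine=None, mask=None) -> VolumeMap:
    affine = np.diag([3.0, 3.0, 3.0, 1.0]) if affine is None else affine
    mask = np.ones(shape, bool) if mask is None else mask
    return VolumeMap(np.full(shape, float(value)), affine, mask)


def volume_from_series(series, shape=(4, 4, 4), affine=None) -> Volume4D:
    """A 4-D volume where every voxel carries the same time series."""
    series = np.asarray(series, float)
    data = np.broadcast_to(series, (*shape, series.size)).copy()
    affine = np.eye(4) if affine is None else affine
    return Volume4D(data=data, affine=affine, tr_seconds=3.0)
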