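import numpy as np
import pytest

from dddthresh import (
    ROI,
    ROISet,
    ConnectivityMatrix,
    Streamline,
    Tractogram,
    load_language_distances,
)


@pytest.fixture(scope="session")
def language_distances():
    return load_language_distances()


@pytest.fixture
def two_rois():
    return ROISet(
        [
            ROI("A", (0.0, 0.0, 0.0), 8.0),
            ROI("B", (0.0, 0.0, 40.0), 8.0),
        ]
    )


@pytest.fixture
def three_rois():
    return ROISet(
        [
            ROI("A", (0.0, 0.0, 0.0), 8.0),
            ROI("B", (0.0, 0.0, 40.0), 8.0),
            ROI("C", (40.0, 0.0, 0.0), 8.0),
        ]
    )


def make_streamline(p0, p1, n_points=5):
    """Straight polyline between two mm points."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    ts = np.linspace(0, 1, n_points)
    return Streamline(p0[None, :] + ts[:, None] * (p1 - p0)[None, :])


def make_tractogram(segments, subject_id="sub", space_tag="mni"):
    return Tractogram(
        subject_id=subject_id,
        streamlines=[make_streamline(a, b) for a, b in segments],
        space_tag=space_tag,
    )


def random_connectivity(n, rng, roi_ids=None):
    """Random symmetric score matrix with zero diagonal."""
    vals = rng.random((n, n)) * 0.5
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    ids = roi_ids or [f"r{i}" for i in range(n)]
    return ConnectivityMatrix(values=vals, roi_ids=ids)
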