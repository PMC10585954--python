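import numpy as np
import pytest

from smpull.synth import OpticsModel, aggregate_from_targets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_optics():
    """Desk-scale optics: small field, few frames, study-scale noise levels."""
    return OpticsModel(fov_px=128, frame_count=10)


@pytest.fixture
def blob_factory(rng):
    """Aggregates at requested (perimeter, circularity), seeded."""

    def make(perimeter_um, circularity, centroid_nm=(2000.0, 2000.0), **kw):
        return aggregate_from_targets(perimeter_um, circularity, centroid_nm, rng, **kw)

    return make


def match_points(detected, truth, max_dist):
    """Greedy one-to-one matching; returns (n_matched, recall, precision)."""
    detected = np.atleast_2d(np.asarray(detected, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if len(detected) == 0 or len(truth) == 0:
        return 0, 0.0, 0.0
    d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    n_match = 0
    used_d, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > max_dist:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n_match += 1
    return n_match, n_match / len(truth), n_match / len(detected)
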