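"""Spot detection: labelling oracle, intensity conservation, count metrics."""

import numpy as np
import pandas as pd
import pytest

from smpull.dlim import (
    ImageStack,
    Spot,
    SpotDetectionParams,
    average_stack,
    counts_per_sample,
    detect_spots,
    high_intensity_fraction,
    spot_intensity,
)
from smpull.errors import BoundsError, UndefinedFractionError, ValidationError
from smpull.synth import OpticsModel, simulate_dlim_stack


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Brute-force BFS labelling oracle, independent of scipy."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                queue = [(r, c)]
                labels[r, c] = nxt
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2] and labels[r2, c2] == 0:
                            labels[r2, c2] = nxt
                            queue.append((r2, c2))
    return labels


def components_as_sets(labels: np.ndarray) -> set[frozenset]:
    return {
        frozenset(zip(*np.nonzero(labels == k))) for k in range(1, labels.max() + 1)
    }


# ---------------------------------------------------------------- averaging

def test_average_of_single_frame_is_identity(rng):
    img = rng.uniform(0, 100, (20, 20)).astype(np.float32)
    stack = ImageStack(img[None], 103.5)
    np.testing.assert_array_equal(average_stack(stack), img)


def test_average_of_constant_stack(rng):
    stack = ImageStack(np.full((7, 16, 16), 3.5), 103.5)
    np.testing.assert_allclose(average_stack(stack), 3.5)


def test_averaging_shrinks_noise_by_sqrt_frames(rng):
    mean_field = rng.uniform(50, 60, (64, 64))
    frames = mean_field[None] + rng.normal(0, 5.0, (50, 64, 64))
    stack = ImageStack(np.clip(frames, 0, None), 103.5)
    resid = average_stack(stack) - mean_field
    assert resid.std() == pytest.approx(5.0 / np.sqrt(50), rel=0.15)


def test_empty_stack_rejected():
    with pytest.raises(ValidationError):
        ImageStack(np.zeros((0, 16, 16)), 103.5)


# ---------------------------------------------------------------- detection

def test_all_zero_image_yields_no_spots():
    assert detect_spots(np.zeros((32, 32))) == []


def test_disjoint_and_touching_discs():
    img = np.zeros((64, 64))
    yy, xx = np.mgrid[:64, :64]
    img[(yy - 16) ** 2 + (xx - 16) ** 2 <= 9] = 100.0
    img[(yy - 40) ** 2 + (xx - 40) ** 2 <= 9] = 100.0
    assert len(detect_spots(img)) == 2
    img2 = np.zeros((64, 64))
    img2[(yy - 20) ** 2 + (xx - 20) ** 2 <= 25] = 100.0
    img2[(yy - 26) ** 2 + (xx - 26) ** 2 <= 25] = 100.0  # overlapping -> one component
    assert len(detect_spots(img2, SpotDetectionParams(max_area_px=500))) == 1


def test_nonfinite_pixels_rejected():
    img = np.zeros((32, 32))
    img[3, 3] = np.nan
    with pytest.raises(ValidationError):
        detect_spots(img)


@pytest.mark.parametrize("connectivity", [4, 8])
def test_labelling_matches_flood_fill_oracle(connectivity, rng):
    params = SpotDetectionParams(connectivity=connectivity, min_area_px=1, max_area_px=32 * 32)
    for _ in range(50):
        mask = rng.random((32, 32)) < 0.35
        img = mask.astype(float)  # bg=0, MAD=0 -> threshold at 0, mask recovered
        spots = detect_spots(img, params)
        got = {frozenset(zip(s.rows.tolist(), s.cols.tolist())) for s in spots}
        want = components_as_sets(flood_fill_labels(mask, connectivity))
        assert got == want


def test_spot_pixels_disjoint_and_above_threshold(rng):
    img = rng.gamma(2.0, 10.0, (64, 64))
    img[10:13, 10:13] += 500
    img[40:42, 50:52] += 800
    params = SpotDetectionParams()
    spots = detect_spots(img, params)
    assert spots
    seen = set()
    from smpull.dlim import robust_background

    bg, sd = robust_background(img)
    for s in spots:
        px = set(zip(s.rows.tolist(), s.cols.tolist()))
        assert not (px & seen)
        seen |= px
        assert all(img[r, c] > bg + params.threshold_k * sd for r, c in px)


def test_detection_translation_equivariance():
    img = np.zeros((64, 64))
    img[20:23, 20:23] = 50.0
    shifted = np.roll(img, (7, 11), axis=(0, 1))
    s0 = detect_spots(img)[0]
    s1 = detect_spots(shifted)[0]
    assert s1.centroid_px[0] == pytest.approx(s0.centroid_px[0] + 7)
    assert s1.centroid_px[1] == pytest.approx(s0.centroid_px[1] + 11)


def test_raising_threshold_never_adds_spots(rng):
    img = rng.gamma(2.0, 10.0, (64, 64))
    for _ in range(4):
        r, c = rng.integers(5, 59, 2)
        img[r : r + 2, c : c + 2] += rng.uniform(30, 300)
    counts = [
        len(detect_spots(img, SpotDetectionParams(threshold_k=k, min_area_px=1)))
        for k in (2.0, 3.0, 4.0, 6.0, 10.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_recall_and_precision_on_synthetic_fov(rng):
    """Detection recovers nearly all simulated emitters at high SNR."""
    from smpull.synth import aggregate_from_targets
    from conftest import match_points

    optics = OpticsModel(fov_px=256, frame_count=20)
    fov_nm = optics.fov_px * optics.pixel_size_nm
    truth = [
        aggregate_from_targets(0.2, 0.7, rng.uniform(0.04 * fov_nm, 0.96 * fov_nm, 2), rng)
        for _ in range(50)
    ]
    stack = simulate_dlim_stack(truth, optics, seed=17)
    spots = detect_spots(average_stack(stack))
    det = [(s.centroid_px[1], s.centroid_px[0]) for s in spots]
    tr = [a.centroid_nm / optics.pixel_size_nm - 0.5 for a in truth]
    _, recall, precision = match_points(det, tr, max_dist=3.0)
    assert recall >= 0.95
    assert precision >= 0.95


# ---------------------------------------------------------------- intensity

def test_intensity_on_zero_background_is_total_signal():
    img = np.zeros((32, 32))
    img[10:13, 10:13] = 7.0
    spot = detect_spots(img, SpotDetectionParams(min_area_px=1))[0]
    assert spot.integrated_intensity_au == pytest.approx(63.0)


def test_intensity_of_uniform_image_is_zero():
    img = np.full((32, 32), 20.0)
    rows, cols = np.mgrid[10:13, 10:13]
    spot = Spot(rows.ravel(), cols.ravel(), (11, 11), 9, 0.0)
    assert spot_intensity(spot, img) == 0.0


def test_intensity_recovers_assigned_brightness(small_optics, blob_factory):
    import dataclasses

    optics = dataclasses.replace(small_optics, background_rate=0.0, read_noise=0.0)
    agg = blob_factory(0.2, 0.8, centroid_nm=(6000, 7000))
    stack = simulate_dlim_stack([agg], optics, seed=3, brightness_au=[50_000.0], noise=False)
    img = average_stack(stack)
    spots = detect_spots(img)
    assert len(spots) == 1
    assert spots[0].integrated_intensity_au == pytest.approx(50_000.0, rel=0.01)


def test_out_of_bounds_spot_rejected():
    spot = Spot(np.array([40]), np.array([40]), (40, 40), 1, 0.0)
    with pytest.raises(BoundsError):
        spot_intensity(spot, np.zeros((32, 32)))


# ------------------------------------------------------------------ metrics

def test_high_intensity_fraction_direct_count():
    assert high_intensity_fraction([10_000.0, 20_000.0, 30_000.0]) == pytest.approx(1 / 3)
    assert high_intensity_fraction([0.0, 0.0, 0.0]) == 0.0


def test_high_intensity_fraction_empty_rejected():
    with pytest.raises(UndefinedFractionError):
        high_intensity_fraction([])


def test_high_intensity_fraction_matches_quantile_construction(rng):
    """When the cut sits at the 75th percentile the fraction approaches 0.25."""
    values = 25_000.0 * np.exp(0.5 * (rng.standard_normal(20_000) - 0.6744898))
    frac = high_intensity_fraction(values)
    se = np.sqrt(0.25 * 0.75 / 20_000)
    assert frac == pytest.approx(0.25, abs=2 * se + 0.005)


def test_counts_per_sample():
    df = pd.DataFrame(
        {
            "channel": ["alpha_syn", "alpha_syn", "abeta"],
            "n_spots": [100, 140, 3],
        }
    )
    out = counts_per_sample(df)
    assert out["alpha_syn"] == 120
    assert out["abeta"] == 3
    with pytest.raises(ValidationError):
        counts_per_sample(df[df["channel"] == "abeta"])
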