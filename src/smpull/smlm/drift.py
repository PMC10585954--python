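"""Stage-drift estimation and correction for localization tables.

The trajectory is recovered by redundant cross-correlation: localizations
are split into time bins, each bin is rendered as a smoothed 2-D histogram,
every bin pair is registered by sub-pixel phase cross-correlation, and the
overdetermined pairwise shifts are solved in least squares for one offset
per bin. Per-frame drift is linear interpolation between bin centres,
anchored at zero for the first bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = ["DriftParams", "correct_drift"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftParams:
    n_time_bins: int = 15
    sr_pixel_nm: float = 20.0
    smooth_px: float = 1.0
    min_locs_per_bin: int = 50
    upsample: int = 100


def _render_bin(sub: pd.DataFrame, edges_x, edges_y, smooth_px: float) -> np.ndarray:
    hist, _, _ = np.histogram2d(sub["y_nm"], sub["x_nm"], bins=(edges_y, edges_x))
    return ndimage.gaussian_filter(hist, smooth_px)


def correct_drift(
    locs: pd.DataFrame, params: DriftParams = DriftParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and subtract drift; returns (corrected table, trajectory).

    The trajectory frame is the full acquisition (one row per frame with
    dx_nm / dy_nm). When any time bin is too sparse to register the input is
    returned unchanged with a zero trajectory and a warning.
    """
    locs = locs.reset_index(drop=True)
    n_frames = int(locs["frame"].max()) if len(locs) else 0
    zero = pd.DataFrame(
        {"frame": np.arange(1, n_frames + 1), "dx_nm": 0.0, "dy_nm": 0.0}
    )
    if len(locs) < params.min_locs_per_bin * 2 or params.n_time_bins < 2:
        log.warning("too few localizations for drift correction; returning input unchanged")
        return locs.copy(), zero

    edges_f = np.linspace(locs["frame"].min() - 0.5, locs["frame"].max() + 0.5, params.n_time_bins + 1)
    bin_of = np.digitize(locs["frame"], edges_f) - 1
    bin_of = np.clip(bin_of, 0, params.n_time_bins - 1)
    counts = np.bincount(bin_of, minlength=params.n_time_bins)
    if (counts < params.min_locs_per_bin).any():
        log.warning("sparse time bin (min %d locs); returning input unchanged", counts.min())
        return locs.copy(), zero

    pad = 5 * params.sr_pixel_nm
    x0, x1 = locs["x_nm"].min() - pad, locs["x_nm"].max() + pad
    y0, y1 = locs["y_nm"].min() - pad, locs["y_nm"].max() + pad
    edges_x = np.arange(x0, x1 + params.sr_pixel_nm, params.sr_pixel_nm)
    edges_y = np.arange(y0, y1 + params.sr_pixel_nm, params.sr_pixel_nm)

    imgs = [
        _render_bin(locs[bin_of == b], edges_x, edges_y, params.smooth_px)
        for b in range(params.n_time_bins)
    ]

    # redundant pairwise registration: shift_ij ≈ d_i - d_j (row, col)
    pairs, shifts = [], []
    for i in range(params.n_time_bins):
        for j in range(i + 1, params.n_time_bins):
            shift, _, _ = phase_cross_correlation(
                imgs[i], imgs[j], upsample_factor=params.upsample, normalization=None
            )
            pairs.append((i, j))
            shifts.append(shift)
    shifts = np.asarray(shifts)  # (n_pairs, 2): moving j into reference i

    a = np.zeros((len(pairs), params.n_time_bins))
    for k, (i, j) in enumerate(pairs):
        a[k, i] = 1.0
        a[k, j] = -1.0
    # anchor the first bin at zero drift
    a = a[:, 1:]
    d_rc = np.zeros((params.n_time_bins, 2))
    for axis in range(2):
        sol, *_ = np.linalg.lstsq(a, shifts[:, axis], rcond=None)
        d_rc[1:, axis] = sol
    d_nm = d_rc[:, ::-1] * params.sr_pixel_nm  # (dx, dy) per bin

    centers_f = 0.5 * (edges_f[:-1] + edges_f[1:])
    frames = np.arange(1, n_frames + 1, dtype=float)
    dx = np.interp(frames, centers_f, d_nm[:, 0])
    dy = np.interp(frames, centers_f, d_nm[:, 1])

    corrected = locs.copy()
    fidx = locs["frame"].to_numpy().astype(int) - 1
    corrected["x_nm"] = corrected["x_nm"] - dx[fidx]
    corrected["y_nm"] = corrected["y_nm"] - dy[fidx]
    traj = pd.DataFrame({"frame": frames.astype(int), "dx_nm": dx, "dy_nm": dy})
    return corrected, traj
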