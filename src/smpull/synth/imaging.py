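"""Camera and blinking-emitter simulators.

Two acquisition modes are emulated. In the diffraction-limited mode every
aggregate emits steadily through a short stack (default 50 frames at 50 ms),
its brightness spread over its binding sites and blurred by a Gaussian PSF.
In the dSTORM mode individual binding sites blink stochastically across
thousands of short frames (default 15 ms); the simulator can emit either the
localization stream directly (ground-truth positions + drift + localization
error) or the raw sparse-emitter frames for testing the fitting stage.

The camera model is linear: ADU = gain · (Poisson(photons) + read noise),
with no pixel crosstalk or EM excess noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ..dlim import ImageStack
from ..errors import ValidationError
from .shapes import GroundTruthAggregate

__all__ = [
    "OpticsModel",
    "BlinkModel",
    "make_drift",
    "simulate_dlim_stack",
    "simulate_localizations",
    "simulate_storm_stack",
    "LOC_COLUMNS",
]

LOC_COLUMNS = ["frame", "x_nm", "y_nm", "sigma_nm", "intensity_photons", "uncertainty_nm"]


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition geometry and camera noise for one imaging mode."""

    pixel_size_nm: float = 103.5
    psf_sigma_px: float = 1.0          # ≈ 0.21·λ/NA for AF647 on a 1.49 NA TIRF objective
    frame_count: int = 50
    exposure_ms: float = 50.0
    fov_px: int = 483                  # ~2500 µm² at 103.5 nm pixels
    background_rate: float = 50.0      # photons / px / frame
    read_noise: float = 1.5            # electrons RMS
    gain: float = 10.0                 # A.U. / photon

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.psf_sigma_px <= 0:
            raise ValidationError("pixel size and PSF sigma must be positive")
        if self.frame_count < 1:
            raise ValidationError("frame_count must be >= 1")
        if self.fov_px < 16:
            raise ValidationError("fov_px must be >= 16")
        if self.background_rate < 0 or self.read_noise < 0 or self.gain <= 0:
            raise ValidationError("noise parameters must be non-negative and gain positive")

    @classmethod
    def dstorm(cls, **overrides) -> "OpticsModel":
        """Defaults for the blinking mode (15 ms exposure, thousands of frames)."""
        base = dict(frame_count=7000, exposure_ms=15.0, background_rate=20.0)
        base.update(overrides)
        return cls(**base)


def make_drift(
    kind: str = "linear",
    total_nm: float = 100.0,
    amplitude_nm: float = 50.0,
    periods: float = 1.0,
    direction_deg: float = 30.0,
) -> Callable[[np.ndarray, int], np.ndarray]:
    """Return drift(frames, n_frames) -> (n, 2) nm displacement.

    ``linear`` accumulates ``total_nm`` over the acquisition along
    ``direction_deg``; ``sine`` oscillates with the given amplitude;
    ``none`` is the null trajectory.
    """
    ang = np.deg2rad(direction_deg)
    u = np.array([np.cos(ang), np.sin(ang)])

    def drift(frames: np.ndarray, n_frames: int) -> np.ndarray:
        t = (np.asarray(frames, dtype=float) - 1.0) / max(n_frames - 1, 1)
        if kind == "none":
            return np.zeros((len(t), 2))
        if kind == "linear":
            return total_nm * t[:, None] * u[None, :]
        if kind == "sine":
            return amplitude_nm * np.sin(2.0 * np.pi * periods * t)[:, None] * u[None, :]
        raise ValidationError(f"unknown drift kind {kind!r}")

    return drift


@dataclass(frozen=True)
class BlinkModel:
    """Stochastic blinking of the reporter fluorophores on binding sites."""

    mean_bursts_per_site: float = 20.0
    localization_precision_nm: float = 20.0
    mean_photons_per_burst: float = 1000.0
    drift: Callable[[np.ndarray, int], np.ndarray] | None = None
    psf_sigma_nm: float = 130.0

    def __post_init__(self) -> None:
        if self.mean_bursts_per_site < 0:
            raise ValidationError("mean bursts per site must be >= 0")
        if self.localization_precision_nm < 0:
            raise ValidationError("localization precision must be >= 0")


def _splat_gaussians(shape, centers_px, sigma_px, weights, truncate: float = 4.0) -> np.ndarray:
    """Accumulate normalised Gaussian kernels onto a grid.

    ``centers_px`` are (n, 2) in (row, col) pixel coordinates where integer
    positions sit at pixel centres. Kernel mass is normalised before placing,
    so the image total equals ``weights.sum()`` up to boundary truncation.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=float)
    centers = np.atleast_2d(np.asarray(centers_px, dtype=float))
    sigmas = np.broadcast_to(np.asarray(sigma_px, dtype=float), (len(centers),))
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (len(centers),))
    for (r0, c0), s, wgt in zip(centers, sigmas, weights):
        rad = max(1, int(np.ceil(truncate * s)))
        ri = int(round(r0))
        ci = int(round(c0))
        rows = np.arange(ri - rad, ri + rad + 1)
        cols = np.arange(ci - rad, ci + rad + 1)
        kr = np.exp(-0.5 * ((rows - r0) / s) ** 2)
        kc = np.exp(-0.5 * ((cols - c0) / s) ** 2)
        kern = np.outer(kr, kc)
        ksum = kern.sum()
        if ksum <= 0:
            continue
        kern *= wgt / ksum
        rsel = (rows >= 0) & (rows < h)
        csel = (cols >= 0) & (cols < w)
        if rsel.any() and csel.any():
            out[np.ix_(rows[rsel], cols[csel])] += kern[np.ix_(rsel, csel)]
    return out


def simulate_dlim_stack(
    truth: Sequence[GroundTruthAggregate],
    optics: OpticsModel,
    seed: int,
    brightness_au: np.ndarray | None = None,
    noise: bool = True,
) -> ImageStack:
    """Render a diffraction-limited stack from ground-truth aggregates.

    Each aggregate's per-frame brightness (A.U.) is divided equally over its
    binding sites and blurred with the Gaussian PSF; frames share the same
    expected image and differ only in noise. With ``noise=False`` the frames
    equal the expected photon image scaled by the gain (no Poisson draw),
    which conserves total signal exactly up to PSF truncation.
    """
    rng = np.random.default_rng(seed)
    fov_nm = optics.fov_px * optics.pixel_size_nm
    for agg in truth:
        if np.any(agg.centroid_nm < 0) or np.any(agg.centroid_nm > fov_nm):
            raise ValidationError("aggregate centroid outside the field of view")

    if brightness_au is None:
        # lognormal with 75th percentile near the 25,000 A.U. high-intensity cut
        brightness_au = 18_000.0 * np.exp(0.5 * rng.standard_normal(len(truth)))
    brightness_au = np.asarray(brightness_au, dtype=float)
    if len(brightness_au) != len(truth):
        raise ValidationError("need one brightness per aggregate")

    signal_photons = np.zeros((optics.fov_px, optics.fov_px), dtype=float)
    for agg, b in zip(truth, brightness_au):
        centers = agg.binding_sites_nm[:, ::-1] / optics.pixel_size_nm - 0.5  # (x,y)->(row,col)
        per_site = b / optics.gain / agg.n_binding_sites
        signal_photons += _splat_gaussians(
            signal_photons.shape, centers, optics.psf_sigma_px, np.full(agg.n_binding_sites, per_site)
        )

    expected = signal_photons + optics.background_rate
    frames = np.empty((optics.frame_count,) + expected.shape, dtype=np.float32)
    for t in range(optics.frame_count):
        if noise:
            photons = rng.poisson(expected).astype(float)
            photons += optics.read_noise * rng.standard_normal(expected.shape)
        else:
            photons = expected
        frames[t] = np.clip(photons * optics.gain, 0.0, None)

    meta = {
        "mode": "dlim",
        "seed": int(seed),
        "exposure_ms": optics.exposure_ms,
        "brightness_au": [float(b) for b in brightness_au],
    }
    return ImageStack(frames=frames, pixel_size_nm=optics.pixel_size_nm, metadata=meta)


def simulate_localizations(
    truth: Sequence[GroundTruthAggregate],
    blink: BlinkModel,
    n_frames: int,
    seed: int,
) -> pd.DataFrame:
    """Generate the blink localization stream for a field of view.

    Every binding site fires Poisson(mean_bursts_per_site) times at uniformly
    random frames; each blink is displaced by the stage drift at its frame
    plus isotropic Gaussian localization error. Rows are sorted by frame.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    sites = (
        np.vstack([agg.binding_sites_nm for agg in truth]) if truth else np.empty((0, 2))
    )
    n_sites = len(sites)
    bursts = rng.poisson(blink.mean_bursts_per_site, size=n_sites) if n_sites else np.empty(0, int)
    total = int(bursts.sum())
    if total == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS}).astype({"frame": int})

    site_idx = np.repeat(np.arange(n_sites), bursts)
    frames = rng.integers(1, n_frames + 1, size=total)
    pos = sites[site_idx].astype(float)
    if blink.drift is not None:
        pos = pos + blink.drift(frames, n_frames)
    pos += blink.localization_precision_nm * rng.standard_normal((total, 2))

    photons = blink.mean_photons_per_burst * np.exp(
        0.3 * rng.standard_normal(total) - 0.5 * 0.3**2
    )
    unc = blink.localization_precision_nm * np.sqrt(blink.mean_photons_per_burst / photons)
    if blink.localization_precision_nm == 0:
        unc = np.zeros(total)

    df = pd.DataFrame(
        {
            "frame": frames,
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "sigma_nm": np.full(total, blink.psf_sigma_nm),
            "intensity_photons": photons,
            "uncertainty_nm": unc,
        }
    )
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def simulate_storm_stack(
    locs: pd.DataFrame,
    optics: OpticsModel,
    seed: int,
    n_frames: int | None = None,
    noise: bool = True,
) -> ImageStack:
    """Render sparse-emitter camera frames from a localization stream.

    Used to exercise the frame-fitting stage against known emitter positions;
    each blink appears in exactly one frame as a PSF-blurred burst of its
    photon count.
    """
    rng = np.random.default_rng(seed)
    if n_frames is None:
        n_frames = int(locs["frame"].max()) if len(locs) else optics.frame_count
    frames = np.empty((n_frames, optics.fov_px, optics.fov_px), dtype=np.float32)
    by_frame = locs.groupby("frame") if len(locs) else {}
    groups = {int(k): v for k, v in by_frame} if len(locs) else {}
    for t in range(1, n_frames + 1):
        img = np.full((optics.fov_px, optics.fov_px), float(optics.background_rate))
        sub = groups.get(t)
        if sub is not None:
            centers = np.column_stack([sub["y_nm"], sub["x_nm"]]) / optics.pixel_size_nm - 0.5
            img += _splat_gaussians(
                img.shape, centers, optics.psf_sigma_px, sub["intensity_photons"].to_numpy()
            )
        if noise:
            img = rng.poisson(img).astype(float) + optics.read_noise * rng.standard_normal(img.shape)
        frames[t - 1] = np.clip(img * optics.gain, 0.0, None)
    return ImageStack(frames=frames, pixel_size_nm=optics.pixel_size_nm, metadata={"mode": "dstorm"})
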