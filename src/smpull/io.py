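"""Readers/writers for the formats the pipeline exchanges.

Image stacks are multi-page 16-bit TIFF with the pixel size stored in the
image description (JSON). Localization tables use the common SMLM CSV
dialect with bracketed unit headers (``frame, x [nm], y [nm], sigma [nm],
intensity [photon], uncertainty [nm]``); internally the columns are plain
identifiers (x_nm, y_nm, ...). All CSV output uses '.' decimals, UTF-8 and
a fixed float format so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dlim import ImageStack
from .errors import ConfigError, FormatError
from .synth.imaging import LOC_COLUMNS

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.8g"

# on-disk dialect <-> internal column names
_DIALECT = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "intensity_photons",
    "uncertainty [nm]": "uncertainty_nm",
}
_REQUIRED = ("frame", "x_nm", "y_nm")
_OPTIONAL_DEFAULTS = {"sigma_nm": 130.0, "intensity_photons": np.nan, "uncertainty_nm": 20.0}


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-page uint16 TIFF with JSON metadata."""
    desc = json.dumps({"pixel_size_nm": stack.pixel_size_nm, **{
        k: v for k, v in stack.metadata.items() if isinstance(v, (int, float, str))
    }})
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def read_stack(path, pixel_size_nm: float | None = None) -> ImageStack:
    """Read a multi-page TIFF; pixel size from metadata unless overridden."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray().astype(np.float32)
            desc = tif.pages[0].description
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ConfigError(
            f"{path} carries no pixel-size metadata; pass pixel_size_nm explicitly"
        )
    return ImageStack(frames=frames, pixel_size_nm=float(px), metadata=meta)


def write_localizations(path, locs: pd.DataFrame) -> None:
    """Write a localization table in the bracketed-unit CSV dialect."""
    inv = {v: k for k, v in _DIALECT.items()}
    out = locs.rename(columns=inv)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV in either dialect; validates and defaults columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"cannot parse localization CSV {path}: {exc}") from exc
    df = df.rename(columns={k: v for k, v in _DIALECT.items() if k in df.columns})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s) {missing}")
    for col in ("frame", "x_nm", "y_nm", "sigma_nm", "intensity_photons", "uncertainty_nm"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row + 1}")
        df[col] = coerced
    for col, default in _OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            log.warning("%s: column %s missing; defaulting to %s", path, col, default)
            df[col] = default
    ordered = [c for c in LOC_COLUMNS if c in df.columns]
    extras = [c for c in df.columns if c not in ordered]
    df = df[ordered + extras]
    df["frame"] = df["frame"].astype(int)
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """Deterministic CSV writer used for every metrics/report table."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
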