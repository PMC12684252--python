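"""Reading and writing movies, masks and tables.

Movies and label masks travel as multi-page / single-page 16-bit TIFF
with a JSON metadata sidecar; localization, trajectory and truth tables
are plain CSV.  All pixel coordinates are 0-based with the origin at the
centre of pixel (0, 0) and x along columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .models import CameraModel
from .simulate import Movie

__all__ = ["write_movie", "read_movie", "write_mask", "read_mask"]


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write the frames as multi-page 16-bit TIFF plus a .json sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    meta = {
        "pixel_size_nm": movie.pixel_size_nm,
        "frame_time_s": movie.frame_time_s,
        "pulse_time_s": movie.pulse_time_s,
        "gain": movie.camera.gain,
        "offset": movie.camera.offset,
        "read_noise": movie.camera.read_noise,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    cam = CameraModel(meta["gain"], meta["offset"], meta["read_noise"])
    return Movie(
        data.astype(np.uint16),
        meta["pixel_size_nm"],
        meta["frame_time_s"],
        meta["pulse_time_s"],
        cam,
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint16), photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.uint16)
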