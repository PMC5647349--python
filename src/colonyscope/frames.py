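"""Frame container and on-disk formats.

A *frame* is one 16-bit grayscale bright-field image of a well on a given
day.  Frames are stored as TIFF named ``well{W}_day{D}.tif``; label masks as
16-bit PNG; tabular outputs as CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

FRAME_NAME_RE = re.compile(r"well(?P<well>[A-Za-z0-9]+)_day(?P<day>\d+)\.tiff?$")


@dataclass
class Frame:
    """One acquired image plus its well/day metadata."""

    pixels: np.ndarray  # 2-D, uint16 for raw acquisitions
    well: str = "1"
    day: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def frame_filename(well: str, day: int) -> str:
    return f"well{well}_day{day}.tif"


def parse_frame_filename(name: str) -> tuple[str, int]:
    m = FRAME_NAME_RE.search(str(name))
    if m is None:
        raise ValueError(f"not a canonical frame name: {name!r}")
    return m.group("well"), int(m.group("day"))


def write_frame(frame: Frame, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / frame_filename(frame.well, frame.day)
    tifffile.imwrite(path, np.asarray(frame.pixels))
    return path


def read_frame(path: str | Path) -> Frame:
    path = Path(path)
    well, day = parse_frame_filename(path.name)
    return Frame(pixels=tifffile.imread(path), well=well, day=day)


def read_frames(directory: str | Path) -> list[Frame]:
    """All canonical frames in a directory, sorted by (well, day)."""
    frames = []
    for p in sorted(Path(directory).iterdir()):
        if FRAME_NAME_RE.search(p.name):
            frames.append(read_frame(p))
    frames.sort(key=lambda f: (f.well, f.day))
    return frames


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a label or binary mask as 16-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(mask).astype(np.uint16))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path))
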