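"""File formats: ImageJ-style multi-page TIFF movies and event CSV tables.

Movies are one file per channel with the channel tag as a filename suffix
(``run1_phase.tif``) and TYX axis order. Event tables use the header
``event_id,class,polarity,t_start,t_end,x,y`` with 0-based inclusive frame
spans.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from edamic.synthsample.types import CHANNELS, EventRecord, TimeLapseMovie

EVENT_HEADER = ["event_id", "class", "polarity", "t_start", "t_end", "x", "y"]


def channel_from_path(path) -> str:
    stem = Path(path).stem
    for channel in sorted(CHANNELS, key=len, reverse=True):
        if stem == channel or stem.endswith("_" + channel):
            return channel
    raise ValueError(f"cannot infer channel tag from filename {path!r}")


def movie_path(directory, basename: str, channel: str) -> Path:
    return Path(directory) / f"{basename}_{channel}.tif"


def write_movie(movie: TimeLapseMovie, path) -> Path:
    """Write a movie as an ImageJ-compatible TYX TIFF.

    The frame interval and pixel size ride along in the ImageJ metadata and
    resolution tags; the channel is encoded in the filename.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(movie.frames, np.float32)
    tifffile.imwrite(
        path, frames, imagej=True,
        resolution=(1.0 / movie.pixel_size, 1.0 / movie.pixel_size),
        metadata={"axes": "TYX", "finterval": 1.0 / movie.frame_rate,
                  "unit": "um"},
    )
    return path


def read_movie(path) -> TimeLapseMovie:
    """Read a TYX TIFF written by :func:`write_movie` (lossless)."""
    path = Path(path)
    channel = channel_from_path(path)
    with tifffile.TiffFile(path) as tif:
        if not tif.pages:
            raise ValueError(f"empty TIFF: {path}")
        shapes = [p.shape for p in tif.pages]
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(f"inconsistent page shape at page {i}: "
                                 f"{s} != {shapes[0]}")
        frames = tif.asarray()
        meta = tif.imagej_metadata or {}
        finterval = float(meta.get("finterval", 1.0))
        tags = tif.pages[0].tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            pixel_size = den / num if num else 1.0
        else:
            pixel_size = 1.0
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError(f"empty TIFF: {path}")
    return TimeLapseMovie(frames=frames.astype(np.float64), channel=channel,
                          frame_rate=1.0 / finterval if finterval else 1.0,
                          pixel_size=float(pixel_size))


def write_events(events, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_HEADER)
        for i, ev in enumerate(events):
            writer.writerow([i, ev.event_class, ev.polarity,
                             ev.t_start, ev.t_end, ev.x, ev.y])
    return path


def read_events(path) -> list:
    """Read an event CSV; malformed rows raise with their line number."""
    path = Path(path)
    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != EVENT_HEADER:
            raise ValueError(f"{path}: expected header {','.join(EVENT_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                _, cls, pol, t0, t1, x, y = row
                t0, t1 = int(t0), int(t1)
                x, y = float(x), float(y)
                if t1 < t0:
                    raise ValueError("t_end < t_start")
                if x < 0 or y < 0 or t0 < 0:
                    raise ValueError("negative coordinate")
                events.append(EventRecord(cls, t0, t1, x, y, pol))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return events
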