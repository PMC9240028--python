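"""Motion-energy extraction from video by frame differencing.

Motion energy for a region of interest (ROI) is the number of pixels inside
the ROI whose grayscale value changes by more than ``diff_threshold``
between consecutive frames.  One video with two fixed rectangular ROIs (one
per person) yields one motion-energy time series per person, sampled at the
video frame rate; sample ``i`` is the change between frames ``i`` and
``i + 1``, so a video of ``N`` frames gives series of length ``N - 1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .conventions import ROLE_INSTRUCTOR, ROLE_LEARNER

__all__ = [
    "RoiSpec",
    "MotionSeries",
    "extract_motion_energy",
    "read_motion_file",
    "write_motion_file",
    "iter_frames",
]

# ITU-R BT.601 luma weights; any fixed linear map would do, this is the
# codec-native choice.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Default per-pixel grayscale change (out of 255) below which a pixel does
#: not count as moved; suppresses sensor noise.
DEFAULT_DIFF_THRESHOLD = 12.0


@dataclass(frozen=True)
class RoiSpec:
    """Fixed rectangular region of interest assigned to one person.

    Coordinates are 0-based pixel indices with half-open upper bounds:
    the ROI covers columns ``x0 <= x < x1`` and rows ``y0 <= y < y1``.
    """

    roi_id: str
    role: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.role not in (ROLE_INSTRUCTOR, ROLE_LEARNER):
            raise ValueError(f"role must be instructor/learner, got {self.role!r}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty ROI {self.roi_id!r}: need x0 < x1 and y0 < y1")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"ROI {self.roi_id!r} has negative coordinates")

    @property
    def n_pixels(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def overlaps(self, other: "RoiSpec") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass
class MotionSeries:
    """One ROI's motion-energy values at a fixed sampling rate.

    ``values`` are non-negative for raw motion energy; preprocessing
    (standardization) produces centred values and flips ``standardized``.
    """

    values: np.ndarray
    sampling_rate: float
    roi_id: str = ""
    role: str = ""
    source: str = "video"
    standardized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MotionSeries values must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MotionSeries values must be finite")
        if not self.standardized and len(self.values) and self.values.min() < 0:
            raise ValueError("raw motion energy must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Series duration in seconds."""
        return len(self.values) / self.sampling_rate

    def with_values(self, values: np.ndarray, *, standardized: bool | None = None) -> "MotionSeries":
        std = self.standardized if standardized is None else standardized
        return replace(self, values=np.asarray(values, dtype=float), standardized=std)


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.float32)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[..., :3].astype(np.float32) @ _LUMA.astype(np.float32)
    raise ValueError(f"expected HxW or HxWx3 frame, got shape {frame.shape}")


def iter_frames(path: str | os.PathLike) -> Iterator[np.ndarray]:
    """Yield frames from a video/stack file.

    TIFF stacks go through :mod:`tifffile`; anything else is handed to
    :mod:`imageio`, so supported containers are whatever plugins the
    installation provides.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            for page in tf.pages:
                yield page.asarray()
        return
    import imageio.v3 as iio

    try:
        yield from iio.imiter(str(path))
    except Exception as exc:  # pragma: no cover - codec availability varies
        raise IOError(f"cannot read frames from {path}: {exc}") from exc


def extract_motion_energy(
    video: str | os.PathLike | Iterable[np.ndarray],
    rois: Sequence[RoiSpec],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    *,
    fps: float = 25.0,
    normalize_area: bool = False,
) -> list[MotionSeries]:
    """Frame-difference a video into one motion-energy series per ROI.

    Parameters
    ----------
    video
        Path to a readable video/stack file, or any iterable of frames
        (``HxW`` grayscale or ``HxWx3`` RGB arrays).
    rois
        Non-overlapping rectangles, one per person.
    diff_threshold
        Per-pixel absolute grayscale change (0-255 scale) that must be
        exceeded for the pixel to count as moved.
    fps
        Sampling rate stamped on the output series (the video frame rate).
    normalize_area
        If True, divide counts by the ROI pixel area so differently sized
        ROIs are comparable.  Off by default.

    Returns
    -------
    list of MotionSeries, one per ROI, each of length ``n_frames - 1``.
    """
    if diff_threshold < 0:
        raise ValueError("diff_threshold must be non-negative")
    rois = list(rois)
    if not rois:
        raise ValueError("need at least one ROI")
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            if a.role != b.role and a.overlaps(b):
                raise ValueError(f"ROIs {a.roi_id!r} and {b.roi_id!r} overlap")

    frames: Iterable[np.ndarray]
    if isinstance(video, (str, os.PathLike)):
        frames = iter_frames(video)
    else:
        frames = iter(video)

    counts: list[list[int]] = [[] for _ in rois]
    prev: np.ndarray | None = None
    n_frames = 0
    for idx, frame in enumerate(frames):
        gray = _to_gray(frame)
        n_frames += 1
        for roi in rois:
            if roi.x1 > gray.shape[1] or roi.y1 > gray.shape[0]:
                raise ValueError(
                    f"ROI {roi.roi_id!r} exceeds frame bounds "
                    f"{gray.shape[1]}x{gray.shape[0]} at frame {idx}"
                )
        if prev is not None:
            for k, roi in enumerate(rois):
                d = np.abs(
                    gray[roi.y0 : roi.y1, roi.x0 : roi.x1]
                    - prev[roi.y0 : roi.y1, roi.x0 : roi.x1]
                )
                counts[k].append(int(np.count_nonzero(d > diff_threshold)))
        prev = gray
    if n_frames < 2:
        raise ValueError(f"need at least 2 frames, got {n_frames}")

    out = []
    for roi, c in zip(rois, counts):
        vals = np.asarray(c, dtype=float)
        if normalize_area:
            vals = vals / roi.n_pixels
        out.append(
            MotionSeries(
                values=vals,
                sampling_rate=fps,
                roi_id=roi.roi_id,
                role=roi.role,
                source="video",
            )
        )
    return out


def read_motion_file(
    path: str | os.PathLike,
    sampling_rate: float | None = None,
    *,
    roles: Sequence[str] = (ROLE_INSTRUCTOR, ROLE_LEARNER),
) -> list[MotionSeries]:
    """Read delimited-text motion energy, one column per ROI.

    A header line of the form ``# sampling_rate=25.0`` (written by
    :func:`write_motion_file`) is honoured; otherwise ``sampling_rate``
    must be given.  Columns map to roles in order, instructor first.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_rate = None
    data_lines: list[tuple[int, str]] = []
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "sampling_rate=" in s:
                header_rate = float(s.split("sampling_rate=")[1].split()[0])
            continue
        data_lines.append((ln, s))
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    rate = sampling_rate if sampling_rate is not None else header_rate
    if rate is None:
        raise ValueError(f"{path}: sampling rate neither in header nor given")

    rows = []
    ncol = None
    for ln, s in data_lines:
        parts = s.replace(",", "\t").split()
        if ncol is None:
            ncol = len(parts)
        elif len(parts) != ncol:
            raise ValueError(f"{path}: ragged row at line {ln}")
        try:
            row = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {ln}") from exc
        if any(not np.isfinite(v) for v in row):
            raise ValueError(f"{path}: NaN/inf cell at line {ln}")
        rows.append(row)
    arr = np.asarray(rows, dtype=float)
    series = []
    for k in range(arr.shape[1]):
        role = roles[k] if k < len(roles) else ""
        series.append(
            MotionSeries(
                values=arr[:, k],
                sampling_rate=rate,
                roi_id=f"col{k}",
                role=role,
                source="file",
            )
        )
    return series


def write_motion_file(path: str | os.PathLike, series: Sequence[MotionSeries]) -> None:
    """Write series as tab-delimited columns with a sampling-rate header."""
    series = list(series)
    if not series:
        raise ValueError("nothing to write")
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise ValueError("all series must have equal length")
    rate = series[0].sampling_rate
    cols = "\t".join(s.role or s.roi_id for s in series)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate={rate} columns={cols}\n")
        arr = np.column_stack([s.values for s in series])
        np.savetxt(fh, arr, fmt="%.10g", delimiter="\t")
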