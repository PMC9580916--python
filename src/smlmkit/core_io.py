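"""Shared data model and I/O for SMLM movies and localization tables.

Coordinate convention (used everywhere in this package): camera pixel
``(i, j)`` (row i, column j) spans the half-open square
``[j, j+1) x [i, i+1)`` in ``(x, y)``; the center of pixel ``(0, 0)`` is
``(0.5, 0.5)``.  Frames are 0-based.  Conversion to nanometers multiplies
by ``pixel_size_nm``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Movie",
    "LocalizationTable",
    "DriftTrace",
    "AffineTransform2D",
    "CsvDialect",
    "THUNDERSTORM_DIALECT",
    "read_movie",
    "write_movie",
    "read_localizations",
    "write_localizations",
    "UNASSIGNED",
]

#: Sentinel track id for localizations that belong to no track.
UNASSIGNED = -1

#: Canonical localization-table columns, in on-disk order.
CANONICAL_COLUMNS = ["frame", "x", "y", "intensity", "track_id", "channel"]


@dataclass
class Movie:
    """A raw or processed SMLM movie.

    Parameters
    ----------
    data
        3D intensity array ``(frame, row, col)`` in camera counts.
    pixel_size_nm
        Physical size of one camera pixel, nanometers.
    frame_interval_s
        Time per frame, seconds.
    """

    data: np.ndarray
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3D (frame, row, col); got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all movie dimensions must be >= 1; got shape {self.data.shape}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LocalizationTable:
    """Tabular record of emitter detections.

    The backing :class:`pandas.DataFrame` always carries the canonical
    columns ``frame, x, y, intensity, track_id, channel``; positions are in
    camera-pixel units.  ``track_id`` uses the sentinel ``-1`` for
    unassigned rows so the table stays rectangular.
    """

    df: pd.DataFrame
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.1

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "track_id" not in df.columns:
            df["track_id"] = UNASSIGNED
        if "channel" not in df.columns:
            df["channel"] = 0
        missing = [c for c in ("frame", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"localization table missing mandatory column(s): {missing}")
        if "intensity" not in df.columns:
            df["intensity"] = 0.0
        df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        df["frame"] = df["frame"].astype(np.int64)
        df["track_id"] = df["track_id"].astype(np.int64)
        df["channel"] = df["channel"].astype(np.int64)
        for c in ("x", "y", "intensity"):
            df[c] = df[c].astype(np.float64)
        if len(df):
            if (df["frame"] < 0).any():
                raise ValueError("frame indices must be >= 0")
            if not np.isfinite(df[["x", "y"]].to_numpy()).all():
                raise ValueError("x, y must be finite")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(
        cls,
        frame: Sequence[int],
        x: Sequence[float],
        y: Sequence[float],
        intensity: Sequence[float] | None = None,
        track_id: Sequence[int] | None = None,
        channel: Sequence[int] | None = None,
        pixel_size_nm: float = 100.0,
        frame_interval_s: float = 0.1,
    ) -> "LocalizationTable":
        n = len(np.atleast_1d(frame))
        df = pd.DataFrame(
            {
                "frame": np.asarray(frame, dtype=np.int64),
                "x": np.asarray(x, dtype=np.float64),
                "y": np.asarray(y, dtype=np.float64),
                "intensity": np.zeros(n) if intensity is None else np.asarray(intensity, dtype=np.float64),
                "track_id": np.full(n, UNASSIGNED) if track_id is None else np.asarray(track_id, dtype=np.int64),
                "channel": np.zeros(n, dtype=np.int64) if channel is None else np.asarray(channel, dtype=np.int64),
            }
        )
        return cls(df, pixel_size_nm=pixel_size_nm, frame_interval_s=frame_interval_s)

    @classmethod
    def empty(cls, pixel_size_nm: float = 100.0, frame_interval_s: float = 0.1) -> "LocalizationTable":
        return cls.from_arrays([], [], [], pixel_size_nm=pixel_size_nm, frame_interval_s=frame_interval_s)

    def copy(self) -> "LocalizationTable":
        return replace(self, df=self.df.copy())

    def sorted_by_frame(self) -> "LocalizationTable":
        """Stable sort by frame, preserving original order within a frame."""
        return replace(self, df=self.df.sort_values("frame", kind="stable").reset_index(drop=True))

    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in camera-pixel units."""
        return self.df[["x", "y"]].to_numpy()

    def xy_nm(self) -> np.ndarray:
        return self.xy() * self.pixel_size_nm


@dataclass
class DriftTrace:
    """Per-frame lateral displacement ``(dx, dy)`` in camera-pixel units."""

    dx: np.ndarray
    dy: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=np.float64)
        self.dy = np.asarray(self.dy, dtype=np.float64)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValueError("dx and dy must be 1D arrays of equal length")
        if not (0 <= self.reference_frame < len(self.dx)):
            raise ValueError("reference_frame out of range")
        if abs(self.dx[self.reference_frame]) > 1e-12 or abs(self.dy[self.reference_frame]) > 1e-12:
            raise ValueError("displacement at reference_frame must be (0, 0)")

    def __len__(self) -> int:
        return len(self.dx)

    @classmethod
    def zeros(cls, n_frames: int, reference_frame: int = 0) -> "DriftTrace":
        return cls(np.zeros(n_frames), np.zeros(n_frames), reference_frame)

    def negated(self) -> "DriftTrace":
        return DriftTrace(-self.dx, -self.dy, self.reference_frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.dx)), "dx": self.dx, "dy": self.dy})


@dataclass
class AffineTransform2D:
    """2D affine map ``(x, y) -> (a*x + b*y + tx, c*x + d*y + ty)`` (pixel units)."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.0
    d: float = 1.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.a * self.d - self.b * self.c) <= 1e-12:
            raise ValueError("affine linear part is singular")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        return xy @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        m = np.linalg.inv(self.matrix)
        t = -m @ self.translation
        return AffineTransform2D(m[0, 0], m[0, 1], m[1, 0], m[1, 1], t[0], t[1])

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("a", "b", "c", "d", "tx", "ty")}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "AffineTransform2D":
        return cls(**{k: float(d[k]) for k in ("a", "b", "c", "d", "tx", "ty")})

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "AffineTransform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------

def read_movie(path, pixel_size_nm: float = 100.0, frame_interval_s: float = 0.1) -> Movie:
    """Read a single- or multi-page grayscale TIFF as a :class:`Movie`.

    Intensities are preserved bit-exact.  RGB / multi-sample TIFFs are
    rejected: SMLM cameras produce grayscale stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}; expected grayscale pages")
    # Heuristic: trailing sample axis of 3/4 means RGB(A) pages.
    if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:-1]):
        raise ValueError("RGB/multi-sample TIFF pages are not supported")
    return Movie(data, pixel_size_nm=pixel_size_nm, frame_interval_s=frame_interval_s)


def write_movie(movie: Movie, path) -> None:
    tifffile.imwrite(Path(path), movie.data, photometric="minisblack")


# ---------------------------------------------------------------------------
# Localization-table I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CsvDialect:
    """Column-mapping configuration for localization CSV files.

    ``columns`` maps canonical names (``frame``, ``x``, ``y``, ``intensity``,
    ``track_id``, ``channel``) to the file's column headers.  ``position_unit``
    is ``"px"`` or ``"nm"``; nm positions are divided by ``pixel_size_nm`` on
    read.  ``one_based_frames`` handles RapidSTORM/ThunderSTORM exports whose
    first frame is 1.  ``half_pixel_offset`` adds 0.5 px on read for exports
    whose pixel (0,0) center is at (0.0, 0.0) rather than (0.5, 0.5).
    """

    columns: Mapping[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    position_unit: str = "px"
    one_based_frames: bool = False
    half_pixel_offset: bool = False

    def __post_init__(self) -> None:
        if self.position_unit not in ("px", "nm"):
            raise ValueError("position_unit must be 'px' or 'nm'")


#: ThunderSTORM default export dialect (nm positions, 1-based frames).
THUNDERSTORM_DIALECT = CsvDialect(
    columns={"frame": "frame", "x": "x [nm]", "y": "y [nm]", "intensity": "intensity [photon]"},
    position_unit="nm",
    one_based_frames=True,
)


def read_localizations(
    path,
    dialect: CsvDialect | None = None,
    pixel_size_nm: float = 100.0,
    frame_interval_s: float = 0.1,
) -> LocalizationTable:
    """Read a localization CSV, converting positions to camera-pixel units."""
    dialect = dialect or CsvDialect()
    raw = pd.read_csv(Path(path))
    for canon in ("frame", "x", "y"):
        col = dialect.columns.get(canon)
        if col is None or col not in raw.columns:
            raise ValueError(f"CSV is missing mandatory column for '{canon}' (looked for {col!r})")
    data = {}
    for canon in CANONICAL_COLUMNS:
        col = dialect.columns.get(canon)
        if col is not None and col in raw.columns:
            series = pd.to_numeric(raw[col], errors="coerce")
            bad = series.isna() & raw[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"non-numeric value in column {col!r} at data row {row}")
            data[canon] = series.to_numpy()
    if dialect.position_unit == "nm":
        data["x"] = data["x"] / pixel_size_nm
        data["y"] = data["y"] / pixel_size_nm
    if dialect.one_based_frames and len(raw):
        data["frame"] = data["frame"] - 1
    if dialect.half_pixel_offset:
        data["x"] = data["x"] + 0.5
        data["y"] = data["y"] + 0.5
    n = len(raw)
    return LocalizationTable.from_arrays(
        frame=data.get("frame", np.zeros(n, dtype=int)),
        x=data["x"] if n else [],
        y=data["y"] if n else [],
        intensity=data.get("intensity"),
        track_id=data.get("track_id"),
        channel=data.get("channel"),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
    )


def write_localizations(table: LocalizationTable, path) -> None:
    """Write the canonical CSV, rows sorted by frame (stable)."""
    out = table.sorted_by_frame().df[CANONICAL_COLUMNS]
    out.to_csv(Path(path), index=False)
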