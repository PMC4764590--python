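"""Volume, lattice, annotation and trajectory containers and their on-disk dialects.

Conventions used throughout the package
---------------------------------------
* All coordinates are **world micrometres** with a corner origin: the world
  position of voxel index ``(x, y, z)`` is ``index * voxel_size``.
* Axis order in world space is ``x`` = lateral, ``y`` = dorso-ventral,
  ``z`` = image axial (for twisted volumes) or arclength from the nose
  (for untwisted volumes).
* Volume intensity arrays are indexed ``[z][y][x]`` (the usual image-stack
  layout), with isotropic voxels.  Anisotropic input is rejected rather
  than silently resampled.
* Missing trajectory values are empty CSV cells (NaN in memory); sentinel
  numbers are never used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "ConfigurationError",
    "Volume",
    "Lattice",
    "Annotation",
    "AnnotationTable",
    "TrajectoryTable",
    "read_volume",
    "write_volume",
    "read_lattice",
    "write_lattice",
    "read_annotations",
    "write_annotations",
    "read_trajectories",
    "write_trajectories",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ConfigurationError(ValueError):
    """Required configuration (e.g. voxel size) is missing or invalid."""


# --------------------------------------------------------------------------- #
# Volumes
# --------------------------------------------------------------------------- #

@dataclass
class Volume:
    """A single-channel 3D intensity grid with isotropic voxels.

    Parameters
    ----------
    intensities
        Non-negative scalars indexed ``[z][y][x]``.
    voxel_size
        Micrometres per voxel (isotropic).
    channel_label
        Free-text channel description.
    """

    intensities: np.ndarray
    voxel_size: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise FormatError(
                f"volume must be 3D, got {self.intensities.ndim} dimensions"
            )
        if min(self.intensities.shape) < 1:
            raise FormatError("all three volume dimensions must be >= 1")
        if not (self.voxel_size > 0):
            raise ConfigurationError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_extent(self) -> np.ndarray:
        """Upper corner of the volume in world µm, order (x, y, z)."""
        nz, ny, nx = self.intensities.shape
        return np.array([nx, ny, nz], dtype=float) * self.voxel_size


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a single-channel 3D TIFF with the voxel size in the description."""
    meta = {"voxel_size_um": v.voxel_size, "channel_label": v.channel_label}
    tifffile.imwrite(str(path), v.intensities, description=json.dumps(meta),
                     photometric="minisblack")


def read_volume(path: str | Path, voxel_size: float | None = None) -> Volume:
    """Read a single-channel 3D TIFF stack.

    The voxel size is taken from a JSON ``ImageDescription`` tag written by
    :func:`write_volume`, from a ``<path>.json`` sidecar with a
    ``voxel_size_um`` key, or from the ``voxel_size`` argument.  The reader
    fails rather than guessing.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    if data.ndim == 2:
        raise FormatError(f"{path} is a 2D image; a 3D stack is required")
    if data.ndim != 3:
        raise FormatError(f"{path} has {data.ndim} dimensions; expected 3")

    label = ""
    if voxel_size is None:
        try:
            meta = json.loads(desc)
            voxel_size = float(meta["voxel_size_um"])
            label = str(meta.get("channel_label", ""))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                voxel_size = float(meta["voxel_size_um"])
                label = str(meta.get("channel_label", ""))
    if voxel_size is None:
        raise ConfigurationError(
            f"no voxel size found for {path}: provide TIFF metadata, a "
            f"'{path.name}.json' sidecar, or the voxel_size argument"
        )
    return Volume(intensities=data, voxel_size=float(voxel_size), channel_label=label)


# --------------------------------------------------------------------------- #
# Lattices
# --------------------------------------------------------------------------- #

@dataclass
class Lattice:
    """Ordered left/right marker-pair points spanning nose (index 0) to tail.

    ``left`` and ``right`` are ``(n, 3)`` arrays of world-µm points in
    ``(x, y, z)`` order.  ``labels`` optionally names each pair
    (H0, H1, ..., V6, T, or "bend").
    """

    left: np.ndarray
    right: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float).reshape(-1, 3)
        self.right = np.asarray(self.right, dtype=float).reshape(-1, 3)
        if self.left.shape != self.right.shape:
            raise FormatError("left and right point lists must have equal length")
        if len(self.left) < 2:
            raise FormatError("a lattice needs at least 2 pairs")
        if np.any(np.all(np.isclose(self.left, self.right), axis=1)):
            raise FormatError("left and right points of a pair must be distinct")
        mids = self.midpoints
        if np.any(np.linalg.norm(np.diff(mids, axis=0), axis=1) < 1e-12):
            raise FormatError("consecutive pair midpoints coincide")
        if self.labels is not None and len(self.labels) != len(self.left):
            raise FormatError("labels must match the number of pairs")

    def __len__(self) -> int:
        return len(self.left)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.left + self.right)

    @property
    def widths(self) -> np.ndarray:
        """Left-to-right distance of each pair, µm."""
        return np.linalg.norm(self.right - self.left, axis=1)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Lattice":
        """Rigidly move the lattice: ``p -> R p + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return Lattice(self.left @ R.T + t, self.right @ R.T + t,
                       list(self.labels) if self.labels else None)


_LATTICE_COLUMNS = ["index", "label", "Lx", "Ly", "Lz", "Rx", "Ry", "Rz"]


def write_lattice(l: Lattice, path: str | Path) -> None:
    n = len(l)
    labels = l.labels if l.labels is not None else [""] * n
    df = pd.DataFrame(
        {
            "index": np.arange(n),
            "label": labels,
            "Lx": l.left[:, 0], "Ly": l.left[:, 1], "Lz": l.left[:, 2],
            "Rx": l.right[:, 0], "Ry": l.right[:, 1], "Rz": l.right[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_lattice(path: str | Path) -> Lattice:
    df = _read_csv(path, _LATTICE_COLUMNS)
    coord_cols = _LATTICE_COLUMNS[2:]
    _require_numeric(df, coord_cols, path)
    df = df.sort_values("index")
    labels = ["" if pd.isna(x) else str(x) for x in df["label"]]
    if all(s == "" for s in labels):
        labels = None
    return Lattice(
        left=df[["Lx", "Ly", "Lz"]].to_numpy(float),
        right=df[["Rx", "Ry", "Rz"]].to_numpy(float),
        labels=labels,
    )


# --------------------------------------------------------------------------- #
# Annotations
# --------------------------------------------------------------------------- #

@dataclass
class Annotation:
    name: str
    point: np.ndarray                     # (3,) µm, in `frame`
    frame: str = "twisted"                # "twisted" or "untwisted"
    untwisted: np.ndarray | None = None   # (3,) µm relative to origin, if mapped
    claimed: bool = True                  # False when outside the worm model

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        if self.frame not in ("twisted", "untwisted"):
            raise FormatError(f"unknown frame {self.frame!r} for {self.name!r}")


@dataclass
class AnnotationTable:
    """Named 3D points plus a designated origin (the nose, by convention)."""

    rows: list[Annotation] = field(default_factory=list)
    origin_name: str | None = None

    def __post_init__(self) -> None:
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            raise FormatError("annotation names must be unique")
        if self.origin_name is not None and self.origin_name not in names:
            raise FormatError(f"origin {self.origin_name!r} not among annotations")

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, name: str) -> Annotation:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def origin(self) -> Annotation:
        if self.origin_name is None:
            raise ConfigurationError("no origin row designated")
        return self[self.origin_name]


def write_annotations(a: AnnotationTable, path: str | Path) -> None:
    rows = []
    has_untwisted = any(r.untwisted is not None for r in a.rows)
    for r in a.rows:
        row = {
            "name": r.name,
            "x": r.point[0], "y": r.point[1], "z": r.point[2],
            "frame": r.frame,
        }
        if has_untwisted:
            u = r.untwisted if r.untwisted is not None else [np.nan] * 3
            row.update(ux=u[0], uy=u[1], uz=u[2])
        if r.name == a.origin_name:
            row["frame"] = row["frame"] + ":origin"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_annotations(path: str | Path) -> AnnotationTable:
    df = _read_csv(path, ["name", "x", "y", "z", "frame"], allow_extra=True)
    _require_numeric(df, ["x", "y", "z"], path)
    rows: list[Annotation] = []
    origin_name = None
    has_u = {"ux", "uy", "uz"}.issubset(df.columns)
    for _, rec in df.iterrows():
        frame = str(rec["frame"])
        name = str(rec["name"])
        if frame.endswith(":origin"):
            frame = frame[: -len(":origin")]
            origin_name = name
        u = None
        if has_u and not pd.isna(rec["ux"]):
            u = np.array([rec["ux"], rec["uy"], rec["uz"]], dtype=float)
        ann = Annotation(name=name, point=np.array([rec["x"], rec["y"], rec["z"]]),
                         frame=frame, untwisted=u)
        rows.append(ann)
    return AnnotationTable(rows=rows, origin_name=origin_name)


# --------------------------------------------------------------------------- #
# Trajectories
# --------------------------------------------------------------------------- #

@dataclass
class TrajectoryTable:
    """Per-(embryo, cell) coordinate time series in long format.

    ``data`` has columns ``embryo, cell, time_min, X, Y, Z``; coordinates are
    µm relative to the nose origin of the untwisted frame, gaps are NaN.
    Time within each (embryo, cell) group is strictly increasing on a
    uniform grid.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["embryo", "cell", "time_min", "X", "Y", "Z"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"trajectory table missing columns {missing}")
        for (emb, cell), grp in self.data.groupby(["embryo", "cell"]):
            t = grp["time_min"].to_numpy(float)
            if len(t) > 1:
                dt = np.diff(t)
                if np.any(dt <= 0):
                    raise FormatError(
                        f"time not strictly increasing for {emb}/{cell}")
                if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                    raise FormatError(f"non-uniform time grid for {emb}/{cell}")

    @property
    def embryos(self) -> list:
        return sorted(self.data["embryo"].unique().tolist())

    @property
    def cells(self) -> list[str]:
        return sorted(self.data["cell"].unique().tolist())

    def dt(self, embryo) -> float:
        t = np.unique(self.data.loc[self.data["embryo"] == embryo, "time_min"])
        if len(t) < 2:
            raise ValueError(f"embryo {embryo!r} has fewer than 2 timepoints")
        return float(t[1] - t[0])

    def series(self, embryo, cell: str) -> pd.DataFrame:
        """Time-ordered rows for one (embryo, cell); columns time_min, X, Y, Z."""
        sel = self.data[(self.data["embryo"] == embryo) & (self.data["cell"] == cell)]
        return sel.sort_values("time_min")[["time_min", "X", "Y", "Z"]].reset_index(drop=True)


def write_trajectories(t: TrajectoryTable, path: str | Path) -> None:
    t.data.to_csv(path, index=False, float_format="%.9g",
                  columns=["embryo", "cell", "time_min", "X", "Y", "Z"])


def read_trajectories(path: str | Path) -> TrajectoryTable:
    df = _read_csv(path, ["embryo", "cell", "time_min", "X", "Y", "Z"])
    _require_numeric(df, ["time_min", "X", "Y", "Z"], path, allow_nan=True)
    if df["time_min"].isna().any():
        bad = int(df.index[df["time_min"].isna()][0])
        raise FormatError(f"{path}: missing time value at row {bad}")
    return TrajectoryTable(data=df)


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #

def _read_csv(path: str | Path, columns: Sequence[str], allow_extra: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if not allow_extra:
        extra = [c for c in df.columns if c not in columns]
        if extra:
            raise FormatError(f"{path}: unexpected columns {extra}")
    return df


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path,
                     allow_nan: bool = False) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise FormatError(
                f"{path}: non-numeric value {df[c][row]!r} in column {c!r}, row {row}")
        if not allow_nan and coerced.isna().any() and c != "label":
            row = int(df.index[coerced.isna()][0])
            raise FormatError(f"{path}: missing value in column {c!r}, row {row}")
        df[c] = coerced
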