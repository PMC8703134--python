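"""Multi-channel volumetric stacks, ROIs, and their file formats.

Coordinate conventions used throughout the package:

* voxel indices are 0-based and ordered ``(z, y, x)``;
* ROIs are half-open on every axis (``x_min`` inclusive, ``x_max`` exclusive);
* all physical quantities are in micrometres; the physical position of a voxel
  is ``index * pitch`` laterally and ``z0 + frame * dz`` axially (voxel-centre
  convention);
* channels are identified by their excitation wavelength in nanometres, kept
  as an opaque string label (e.g. ``"405"``, ``"488"``).

Whether "deeper into the sample" corresponds to increasing or decreasing
stage z depends on the microscope geometry (upright vs inverted); it is
recorded as the ``z_orientation`` metadata flag and never assumed.

Stacks are read and written as multi-page TIFF (ImageJ hyperstack layout;
OME-style axis strings are honoured on read).  Acquisition metadata — voxel
pitch, stage origin, channel wavelengths, reference channel — comes from a
sidecar YAML config, which is the normative source; ``write_stack`` also
embeds the metadata as JSON in the ImageJ ``Info`` field so that phantoms
round-trip without a sidecar.

Volumes are held in memory (desk-scale stacks of a few hundred MB at most);
there is no lazy/chunked reading.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError

__all__ = [
    "ChannelStack",
    "MultiChannelStack",
    "BeadROI",
    "StackMetadata",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "load_config",
]

_WRITABLE_DTYPES = ("uint8", "uint16", "float32")


@dataclass(eq=False)
class ChannelStack:
    """One channel's 3D intensity grid plus physical calibration.

    Parameters
    ----------
    voxels
        Non-negative intensity grid indexed ``(z, y, x)``.
    dx, dy, dz
        Voxel pitch in micrometres (all strictly positive).
    z0
        Physical stage position of frame 0 in micrometres.
    channel_id
        Excitation wavelength label in nanometres.
    """

    voxels: np.ndarray
    dx: float
    dy: float
    dz: float
    channel_id: str
    z0: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataError(
                f"channel {self.channel_id!r}: expected a 3D (z, y, x) grid, "
                f"got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise DataError(f"channel {self.channel_id!r}: empty axis in shape {self.voxels.shape}")
        for name, pitch in (("dx", self.dx), ("dy", self.dy), ("dz", self.dz)):
            if not pitch > 0:
                raise DataError(f"channel {self.channel_id!r}: {name} must be > 0, got {pitch}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    def frame_positions(self) -> np.ndarray:
        """Physical stage position of every frame, ``z0 + n*dz`` (μm)."""
        return self.z0 + np.arange(self.nz) * self.dz


@dataclass(eq=False)
class MultiChannelStack:
    """An ordered set of co-acquired channel stacks sharing one voxel grid."""

    channels: tuple[ChannelStack, ...]
    reference_channel: str
    z_orientation: str = "deeper-positive"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if not self.channels:
            raise DataError("a MultiChannelStack needs at least one channel")
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate channel ids: {ids}")
        first = self.channels[0]
        for c in self.channels[1:]:
            if c.shape != first.shape:
                raise DataError(
                    f"channel {c.channel_id!r} shape {c.shape} differs from "
                    f"{first.channel_id!r} shape {first.shape}"
                )
            if (c.dx, c.dy, c.dz, c.z0) != (first.dx, first.dy, first.dz, first.z0):
                raise DataError(f"channel {c.channel_id!r} voxel calibration differs")
        if self.reference_channel not in ids:
            raise DataError(
                f"reference channel {self.reference_channel!r} not among channels {ids}"
            )

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return tuple(c.channel_id for c in self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    def channel(self, channel_id: str) -> ChannelStack:
        for c in self.channels:
            if c.channel_id == channel_id:
                return c
        raise KeyError(channel_id)

    @property
    def reference(self) -> ChannelStack:
        return self.channel(self.reference_channel)

    def with_channel(self, new: ChannelStack) -> "MultiChannelStack":
        """Return a copy with the channel of matching id replaced."""
        chans = tuple(new if c.channel_id == new.channel_id else c for c in self.channels)
        return replace(self, channels=chans)


@dataclass(frozen=True)
class BeadROI:
    """A rectangular region expected to contain exactly one object.

    Bounds are 0-based, half-open voxel indices.  ``z_min``/``z_max`` default
    to the full axial range of whatever stack the ROI is applied to.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    z_min: int | None = None
    z_max: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise DataError(f"ROI {self.label!r}: empty x or y extent")
        if self.x_min < 0 or self.y_min < 0:
            raise DataError(f"ROI {self.label!r}: negative bounds")
        if (self.z_min is None) != (self.z_max is None):
            raise DataError(f"ROI {self.label!r}: z bounds must be given together")
        if self.z_min is not None and not (0 <= self.z_min < self.z_max):  # type: ignore[operator]
            raise DataError(f"ROI {self.label!r}: empty or negative z extent")

    def z_bounds(self, nz: int) -> tuple[int, int]:
        """Resolved half-open z bounds for a stack with ``nz`` frames."""
        if self.z_min is None:
            return 0, nz
        return self.z_min, self.z_max  # type: ignore[return-value]

    def slices(self, nz: int) -> tuple[slice, slice, slice]:
        z0, z1 = self.z_bounds(nz)
        return slice(z0, z1), slice(self.y_min, self.y_max), slice(self.x_min, self.x_max)

    def check_within(self, shape: tuple[int, int, int]) -> None:
        nz, ny, nx = shape
        z0, z1 = self.z_bounds(nz)
        if self.x_max > nx or self.y_max > ny or z1 > nz or z0 < 0:
            raise DataError(
                f"ROI {self.label!r} exceeds grid bounds {shape}: "
                f"x[{self.x_min},{self.x_max}) y[{self.y_min},{self.y_max}) z[{z0},{z1})"
            )


@dataclass
class StackMetadata:
    """Acquisition metadata normally supplied by a sidecar YAML config."""

    dx: float
    dy: float
    dz: float
    channels: list[str]
    reference_channel: str
    z0: float = 0.0
    z_orientation: str = "deeper-positive"
    z_positions: list[float] | None = None

    def __post_init__(self) -> None:
        self.channels = [str(c) for c in self.channels]
        self.reference_channel = str(self.reference_channel)
        if self.reference_channel not in self.channels:
            raise DataError(
                f"reference channel {self.reference_channel!r} not in channels {self.channels}"
            )
        if self.z_positions is not None and len(self.z_positions) >= 2:
            steps = np.diff(np.asarray(self.z_positions, dtype=float))
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise DataError("non-uniform z spacing declared in metadata; only uniform stacks are supported")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "StackMetadata":
        try:
            return cls(
                dx=float(cfg["dx"]),
                dy=float(cfg["dy"]),
                dz=float(cfg["dz"]),
                z0=float(cfg.get("z0", 0.0)),
                channels=list(cfg["channels"]),
                reference_channel=str(cfg["reference_channel"]),
                z_orientation=str(cfg.get("z_orientation", "deeper-positive")),
                z_positions=cfg.get("z_positions"),
            )
        except KeyError as exc:
            raise DataError(f"config missing required key: {exc.args[0]!r}") from exc

    def to_dict(self) -> dict:
        d = {
            "dx": self.dx,
            "dy": self.dy,
            "dz": self.dz,
            "z0": self.z0,
            "channels": list(self.channels),
            "reference_channel": self.reference_channel,
            "z_orientation": self.z_orientation,
        }
        if self.z_positions is not None:
            d["z_positions"] = list(self.z_positions)
        return d


def load_config(path: str | Path) -> dict:
    """Load a YAML sidecar config into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} is not a mapping")
    return cfg


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_stack(stack: MultiChannelStack, path: str | Path) -> None:
    """Write a stack as an ImageJ hyperstack TIFF (axes ZCYX).

    The acquisition metadata is embedded as JSON in the ImageJ ``Info`` field,
    so a stack written here round-trips through :func:`read_stack` without a
    sidecar config.
    """
    path = Path(path)
    if str(path) == "":
        raise DataError("empty output path")
    dtype = stack.channels[0].voxels.dtype
    if dtype.name not in _WRITABLE_DTYPES:
        raise DataError(
            f"dtype {dtype} not supported for ImageJ TIFF; use one of {_WRITABLE_DTYPES}"
        )
    first = stack.channels[0]
    arr = np.stack([c.voxels for c in stack.channels], axis=1)  # (Z, C, Y, X)
    meta = StackMetadata(
        dx=first.dx,
        dy=first.dy,
        dz=first.dz,
        z0=first.z0,
        channels=list(stack.channel_ids),
        reference_channel=stack.reference_channel,
        z_orientation=stack.z_orientation,
    )
    tifffile.imwrite(
        path,
        arr,
        imagej=True,
        resolution=(1.0 / first.dx, 1.0 / first.dy),
        metadata={
            "axes": "ZCYX",
            "spacing": first.dz,
            "unit": "um",
            "Info": json.dumps(meta.to_dict()),
        },
    )


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (C, Z, Y, X), inserting missing axes."""
    axes = axes.upper()
    # squeeze singleton axes we do not model
    for extra in ("S", "T", "Q", "I"):
        while extra in axes:
            i = axes.index(extra)
            if data.shape[i] != 1:
                if extra == "I":
                    # generic 'image' axis: treat as Z if no Z present, else error
                    axes = axes.replace("I", "Z", 1)
                    continue
                raise DataError(f"unsupported non-singleton TIFF axis {extra!r} (axes={axes})")
            data = np.take(data, 0, axis=i)
            axes = axes[:i] + axes[i + 1 :]
    for needed in ("C", "Z"):
        if needed not in axes:
            data = data[np.newaxis]
            axes = needed + axes
    if sorted(axes) != ["C", "X", "Y", "Z"] :
        raise DataError(f"cannot interpret TIFF axes {axes!r}")
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def read_stack(path: str | Path, metadata: StackMetadata | Mapping | None = None) -> MultiChannelStack:
    """Read a multi-page TIFF into a :class:`MultiChannelStack`.

    ``metadata`` (a :class:`StackMetadata` or a config mapping) is the
    normative source of voxel pitch and channel wavelengths.  If omitted, the
    embedded ImageJ ``Info`` JSON written by :func:`write_stack` is used;
    if neither is available this is an error — pitch is never silently
    defaulted.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"stack file not found: {path}")
    if isinstance(metadata, Mapping):
        metadata = StackMetadata.from_mapping(metadata)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ij = tif.imagej_metadata or {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise DataError(f"unreadable TIFF {path}: {exc}") from exc
    if metadata is None:
        info = ij.get("Info")
        if info:
            try:
                metadata = StackMetadata.from_mapping(json.loads(info))
            except (json.JSONDecodeError, DataError):
                metadata = None
        if metadata is None:
            raise DataError(
                f"{path}: no voxel pitch / channel metadata; pass a sidecar config "
                "(dx, dy, dz, channels, reference_channel)"
            )
    data = _axes_to_czyx(data, axes)
    n_chan = data.shape[0]
    if n_chan != len(metadata.channels):
        raise DataError(
            f"{path}: file has {n_chan} channel(s) but config names "
            f"{len(metadata.channels)}: {metadata.channels}"
        )
    channels = tuple(
        ChannelStack(
            voxels=data[i],
            dx=metadata.dx,
            dy=metadata.dy,
            dz=metadata.dz,
            z0=metadata.z0,
            channel_id=cid,
        )
        for i, cid in enumerate(metadata.channels)
    )
    return MultiChannelStack(
        channels=channels,
        reference_channel=metadata.reference_channel,
        z_orientation=metadata.z_orientation,
    )


# ---------------------------------------------------------------------------
# ROI I/O
# ---------------------------------------------------------------------------

_ROI_CSV_COLUMNS = ["label", "x_min", "x_max", "y_min", "y_max"]


def _rois_from_csv(path: Path) -> list[BeadROI]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise DataError(f"malformed ROI CSV {path}: {exc}") from exc
    missing = [c for c in _ROI_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"ROI CSV {path} missing columns {missing}")
    has_z = "z_min" in df.columns and "z_max" in df.columns
    rois = []
    for i, row in df.iterrows():
        kwargs = dict(
            label=str(row["label"]),
            x_min=int(row["x_min"]),
            x_max=int(row["x_max"]),
            y_min=int(row["y_min"]),
            y_max=int(row["y_max"]),
        )
        if has_z and not (pd.isna(row["z_min"]) or pd.isna(row["z_max"])):
            kwargs["z_min"] = int(row["z_min"])
            kwargs["z_max"] = int(row["z_max"])
        try:
            rois.append(BeadROI(**kwargs))
        except DataError as exc:
            raise DataError(f"ROI CSV {path} row {i}: {exc}") from exc
    return rois


# ImageJ .roi layout (rectangles): magic "Iout", int16 version at offset 4,
# uint8 roi type at 6, int16 top/left/bottom/right at 8/10/12/14, big-endian.
# bottom/right are exclusive (top + height, left + width), matching our
# half-open convention directly.
_IJ_RECT = 1


def _roi_from_imagej_bytes(blob: bytes, label: str) -> BeadROI:
    if len(blob) < 16 or blob[:4] != b"Iout":
        raise DataError(f"ImageJ ROI {label!r}: bad magic / truncated header")
    roi_type = blob[6]
    if roi_type != _IJ_RECT:
        raise DataError(
            f"ImageJ ROI {label!r}: type code {roi_type} is not a rectangle; "
            "only rectangular ROIs are supported"
        )
    top, left, bottom, right = struct.unpack(">4h", blob[8:16])
    return BeadROI(x_min=left, x_max=right, y_min=top, y_max=bottom, label=label)


def read_rois(path: str | Path) -> list[BeadROI]:
    """Read ROIs from CSV, a single ImageJ ``.roi``, or an ImageJ ``.zip``.

    The CSV dialect has header ``label,x_min,x_max,y_min,y_max[,z_min,z_max]``;
    omitted z bounds mean the full axial range.  ImageJ ROIs must be
    rectangles; bounds are converted to 0-based half-open indices.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"ROI file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".roi":
        return [_roi_from_imagej_bytes(path.read_bytes(), path.stem)]
    if suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(_roi_from_imagej_bytes(zf.read(name), Path(name).stem))
        if not rois:
            raise DataError(f"{path}: zip contains no .roi entries")
        return rois
    return _rois_from_csv(path)


def write_rois(rois: Sequence[BeadROI], path: str | Path) -> None:
    """Write ROIs in the package's CSV dialect."""
    rows = []
    for roi in rois:
        rows.append(
            {
                "label": roi.label,
                "x_min": roi.x_min,
                "x_max": roi.x_max,
                "y_min": roi.y_min,
                "y_max": roi.y_max,
                "z_min": roi.z_min if roi.z_min is not None else "",
                "z_max": roi.z_max if roi.z_max is not None else "",
            }
        )
    pd.DataFrame(rows, columns=_ROI_CSV_COLUMNS + ["z_min", "z_max"]).to_csv(path, index=False)
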