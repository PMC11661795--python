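"""Image-stack and table I/O.

All format knowledge lives here: grayscale multi-page TIFF in and out
(axis order (z, y, x), pages map to z), RGB overlay TIFFs for manual
proof-reading, and CSV cell tables.  The rest of the package works on the
in-memory containers defined below and never touches files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

CELL_TABLE_COLUMNS = [
    "label",
    "centroid_z",
    "centroid_y",
    "centroid_x",
    "voxels",
    "volume_um3",
    "mean_intensity",
]


class FormatError(ValueError):
    """Raised when an input file is not a grayscale stack of 2-D pages."""


@dataclass
class VoxelGrid:
    """A 3-D scalar intensity volume with voxel spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities; dtype uint8 or uint16 (or any integer/
        float array that fits the declared bit depth).
    dz, dy, dx : float
        Voxel spacing in micrometres.  Anisotropy is allowed and is the
        norm for confocal stacks (z step typically coarser than xy).
    bit_depth : int
        8 or 16; intensities must lie in [0, 2**bit_depth - 1].
    """

    data: np.ndarray
    dz: float = 1.0
    dy: float = 1.0
    dx: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (z, y, x); got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("empty volume (zero pages or zero-sized pages)")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16; got {self.bit_depth}")
        if not (self.dz > 0 and self.dy > 0 and self.dx > 0):
            raise ValueError("voxel spacings dz, dy, dx must all be positive")
        lo = self.data.min()
        hi = self.data.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside the {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dz * self.dy * self.dx

    def astype_native(self) -> np.ndarray:
        """Data cast to the smallest dtype matching ``bit_depth``."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return self.data.astype(dtype, copy=False)

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's spacing and bit depth."""
        return VoxelGrid(data, self.dz, self.dy, self.dx, self.bit_depth)


@dataclass
class LabelVolume:
    """Integer label volume: 0 = background, 1..n_labels = cell regions.

    Labels are dense (no gaps).  Use :meth:`from_labels` to densify an
    arbitrary labelled array.
    """

    labels: np.ndarray
    n_labels: int = field(default=-1)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.n_labels < 0:
            self.n_labels = int(self.labels.max(initial=0))
        present = np.unique(self.labels)
        expected = np.arange(self.n_labels + 1)
        if present[0] == 0:
            dense = len(present) == self.n_labels + 1 and present[-1] == self.n_labels
        else:  # no background voxels at all
            dense = len(present) == self.n_labels and present[-1] == self.n_labels
        if not dense or (present < 0).any():
            raise ValueError(
                f"labels must be exactly {{0..{self.n_labels}}}; found {present[:10]}…"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelVolume":
        """Densify arbitrary non-negative labels to 1..m, order-preserving."""
        labels = np.asarray(labels)
        values = np.unique(labels)
        values = values[values > 0]
        lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
        lut[values] = np.arange(1, len(values) + 1, dtype=np.int32)
        return cls(lut[labels], n_labels=len(values))


def make_cell_table(rows: list[dict] | None = None) -> pd.DataFrame:
    """An empty or populated cell table with the canonical column set."""
    df = pd.DataFrame(rows or [], columns=CELL_TABLE_COLUMNS)
    return df.astype({"label": np.int64, "voxels": np.int64}, errors="ignore")


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort spacing recovery from ImageJ/shaped metadata + resolution tags."""
    try:
        meta = dict(tif.imagej_metadata or {})
        if not meta and tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        dz = float(meta.get("spacing", 0.0))
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if dz > 0 and xres is not None and yres is not None:
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr > 0 and yr > 0:
                return (dz, 1.0 / yr, 1.0 / xr)
    except Exception:  # metadata is advisory only
        pass
    return None


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
) -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF as a :class:`VoxelGrid`.

    Spacing is taken from the ``spacing`` argument when given, else from
    embedded ImageJ/resolution metadata, else defaults to isotropic 1 µm
    with a logged warning so bare test arrays stay usable.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                if getattr(page, "samplesperpixel", 1) != 1:
                    raise FormatError(
                        f"{path}: page {i} has {page.samplesperpixel} samples/pixel "
                        "(RGB/multichannel); grayscale stacks required"
                    )
            # per-page read: immune to the squeezing of singleton axes
            # that series-level reads apply
            data = np.stack([page.asarray() for page in tif.pages])
            meta_spacing = _spacing_from_tiff(tif)
            # the shaped-TIFF writer folds singleton axes into the page;
            # its recorded shape restores them
            if tif.shaped_metadata:
                true_shape = tuple(tif.shaped_metadata[0].get("shape", ()))
                if len(true_shape) == 3 and int(np.prod(true_shape)) == data.size:
                    data = data.reshape(true_shape)
    except FileNotFoundError:
        raise
    except FormatError:
        raise
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D grayscale pages, got shape {data.shape}")

    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    elif np.issubdtype(data.dtype, np.integer) and data.max(initial=0) <= 255:
        bit_depth = 8
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer) and data.max(initial=0) <= 65535:
        bit_depth = 16
        data = data.astype(np.uint16)
    else:
        raise FormatError(f"{path}: unsupported sample dtype {data.dtype}")

    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        logger.warning("%s: no voxel spacing available; assuming isotropic 1 µm", path)
        warnings.warn(f"{path}: no voxel spacing available; assuming isotropic 1 µm")
        spacing = (1.0, 1.0, 1.0)
    dz, dy, dx = spacing
    return VoxelGrid(data, dz, dy, dx, bit_depth)


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as a multi-page grayscale TIFF.

    Round-trip contract: ``read_stack(write_stack(g))`` reproduces the
    voxel data and bit depth exactly, and the spacing via ImageJ metadata.
    """
    path = Path(path)
    data = grid.astype_native()
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(1.0 / grid.dx, 1.0 / grid.dy),
        metadata={"spacing": grid.dz, "unit": "um", "axes": "ZYX"},
    )


def label_boundaries(labels: np.ndarray) -> np.ndarray:
    """Label voxels having a 6-neighbour with a different value."""
    labels = np.asarray(labels)
    boundary = np.zeros(labels.shape, dtype=bool)
    for axis in range(3):
        diff = np.diff(labels, axis=axis) != 0
        lead = [slice(None)] * 3
        trail = [slice(None)] * 3
        lead[axis] = slice(1, None)
        trail[axis] = slice(None, -1)
        boundary[tuple(lead)] |= diff
        boundary[tuple(trail)] |= diff
    return boundary & (labels > 0)


def write_overlay(grid: VoxelGrid, labels: LabelVolume, path: str | Path) -> None:
    """Write an RGB merge of raw signal and label boundaries.

    The raw channel (green) keeps the full dynamic range scaled to 8-bit;
    label boundaries go to the red channel, leaving interiors untouched so
    missed cells can be added by hand in an external viewer.
    """
    if grid.shape != labels.shape:
        raise ValueError(f"shape mismatch: grid {grid.shape} vs labels {labels.shape}")
    scale = max(1, 2**grid.bit_depth - 1)
    raw8 = (grid.data.astype(np.float64) / scale * 255.0).round().astype(np.uint8)
    boundary = label_boundaries(labels.labels)
    rgb = np.zeros(grid.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.where(boundary, 255, 0)
    rgb[..., 1] = raw8
    tifffile.imwrite(Path(path), rgb, photometric="rgb")


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as RFC-4180 CSV, rows ordered by label."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    out = table.loc[:, CELL_TABLE_COLUMNS].sort_values("label")
    out.to_csv(Path(path), index=False, lineterminator="\n")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read back a cell table CSV written by :func:`write_cell_table`."""
    df = pd.read_csv(Path(path))
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cell-table columns {missing}")
    return make_cell_table(df.to_dict("records")) if len(df) else make_cell_table()


def check_connected_labels(volume: LabelVolume, connectivity: int = 26) -> bool:
    """True when every positive label is a single connected component."""
    structure = ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    for lab in range(1, volume.n_labels + 1):
        _, n = ndi.label(volume.labels == lab, structure=structure)
        if n != 1:
            return False
    return True
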