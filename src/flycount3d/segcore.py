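"""Seeded-watershed segmentation of dopaminergic somata in 3-D stacks.

The pipeline targets anti-TH immunostaining, where somata are bright but
diffuse and irregular, so a plain threshold over-merges touching cells.
Stages, in order:

1. median filter — knocks down Poisson shot noise without blurring edges;
2. grayscale closing — fills small dark pits inside somata;
3. dark suppression — very dark voxels are forced to zero and define the
   background mask;
4. inverse-dome seed extraction — the preprocessed image is inverted so
   each bright soma becomes an intensity basin ("inverse dome"); the
   extended h-minima transform flattens shallow minima so that one seed
   survives per cell rather than one per noise wiggle;
5. seeded 3-D watershed — floods the inverted relief from the seeds to
   recover each cell's shape inside the foreground mask.

All morphology acts in voxel units; anisotropy is deliberately NOT
compensated inside the structuring elements (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import ball, local_minima, reconstruction
from skimage.segmentation import watershed

from .volio import LabelVolume, VoxelGrid, make_cell_table

logger = logging.getLogger(__name__)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26; got {connectivity}")


@dataclass
class Dopa3DParams:
    """Tuning knobs of the dopaminergic-soma pipeline.

    Parameters
    ----------
    median_radius : int
        Half-width of the cubic median window per axis ((2r+1)^3 box).
    closing_radius : int
        Radius (voxels) of the ball structuring element for the closing.
    dark_threshold : float
        Intensity below which voxels are zeroed; also defines the
        watershed mask.  Default 75 on the 8-bit scale.
    h : float
        Depth of the extended h-minima transform: basins shallower than
        this (dynamic <= h) are flattened and yield no seed.
    connectivity : int
        6 or 26; neighbourhood for minima detection and component
        labelling.
    invert : bool
        Work on inverted intensity so bright somata become basins.  Leave
        on for bright-signal stacks; off if cells appear dark.
    min_seed_voxels : int
        Seeds smaller than this are discarded as specks.  Default 1 (off):
        the h-minima transform already suppresses noise-induced seeds, and
        genuine small somata produce minima plateaus of only a few voxels.
    watershed_connectivity : int
        6 or 26; neighbourhood for the flood itself (6 leaks least).
    """

    median_radius: int = 1
    closing_radius: int = 1
    dark_threshold: float = 75.0
    h: float = 10.0
    connectivity: int = 26
    invert: bool = True
    min_seed_voxels: int = 1
    watershed_connectivity: int = 6

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.median_radius < 0 or self.closing_radius < 0:
            raise ValueError("filter radii must be >= 0")
        _structure(self.connectivity)
        _structure(self.watershed_connectivity)


@dataclass
class SeedSet:
    """Labelled connected components of the extended-minima mask."""

    seed_labels: np.ndarray
    n_seeds: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.seed_labels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# preprocessing


def median_filter_3d(grid: VoxelGrid, radius: int) -> VoxelGrid:
    """Median over the (2r+1)^3 box neighbourhood; edge replication."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return grid
    out = ndi.median_filter(grid.data, size=2 * radius + 1, mode="nearest")
    return grid.with_data(out)


def closing_3d(grid: VoxelGrid, radius: int) -> VoxelGrid:
    """Grayscale closing (dilation then erosion) with a voxel-unit ball."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return grid
    footprint = ball(radius)
    out = ndi.grey_closing(grid.data, footprint=footprint, mode="nearest")
    return grid.with_data(out)


def suppress_dark(grid: VoxelGrid, dark_threshold: float) -> VoxelGrid:
    """Zero every voxel strictly below ``dark_threshold``."""
    out = np.where(grid.data < dark_threshold, 0, grid.data).astype(grid.data.dtype)
    return grid.with_data(out)


# ---------------------------------------------------------------------------
# h-minima machinery


def reconstruct_by_erosion(
    marker: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Morphological reconstruction by erosion of ``marker`` over ``mask``.

    The limit of iterating "erode marker by the connectivity
    neighbourhood, then pointwise max with mask" until stability.
    Requires marker >= mask pointwise.
    """
    marker = np.asarray(marker, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if marker.shape != mask.shape:
        raise ValueError("marker and mask must have identical shapes")
    if (marker < mask).any():
        raise ValueError("reconstruction by erosion requires marker >= mask pointwise")
    footprint = _structure(connectivity)
    return reconstruction(marker, mask, method="erosion", footprint=footprint)


def hminima_transform(grid_data: np.ndarray, h: float, connectivity: int = 26) -> np.ndarray:
    """Extended h-minima transform: fills every basin of dynamic <= h.

    Defined as the reconstruction by erosion of (f + h) over f.  At h = 0
    it is the identity.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    f = np.asarray(grid_data, dtype=np.float64)
    if h == 0:
        return f.copy()
    return reconstruct_by_erosion(f + h, f, connectivity)


def regional_minima(grid_data: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Mask of connected plateaus with no strictly lower neighbour."""
    f = np.asarray(grid_data, dtype=np.float64)
    if f.min() == f.max():  # constant volume: one global plateau minimum
        return np.ones(f.shape, dtype=bool)
    conn = 3 if connectivity == 26 else 1
    return local_minima(f, connectivity=conn, allow_borders=True)


def extract_seeds(grid: VoxelGrid | np.ndarray, params: Dopa3DParams) -> SeedSet:
    """One seed per inverse dome of the (preprocessed) image.

    If ``params.invert``, the image is inverted first so that bright
    somata become basins; the extended h-minima transform then merges the
    multiple local minima that noise puts inside one cell into a single
    extended minimum, fixing multiple counting, and each resulting
    component becomes one watershed seed.
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    f = data.astype(np.float64)
    if params.invert:
        f = f.max() - f
    flattened = hminima_transform(f, params.h, params.connectivity)
    minima = regional_minima(flattened, params.connectivity)
    if minima.all():
        warnings.warn("uniform relief: the whole volume is one seed (degenerate input)")
    labels, n = ndi.label(minima, structure=_structure(params.connectivity))
    if params.min_seed_voxels > 1 and n:
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        small = counts < params.min_seed_voxels
        small[0] = False
        labels[small[labels]] = 0
        dense = LabelVolume.from_labels(labels)
        return SeedSet(dense.labels, dense.n_labels)
    return SeedSet(labels.astype(np.int32), int(n))


def watershed_3d(
    grid_data: np.ndarray,
    seeds: SeedSet,
    mask: np.ndarray | None = None,
    connectivity: int = 6,
) -> LabelVolume:
    """Marker-controlled watershed flood of ``grid_data`` from ``seeds``.

    Every masked voxel is assigned to exactly one seed; regions are
    connected and contain their seed; voxels outside the mask stay 0.
    Flood order is deterministic (stable priority flood), so repeated
    runs are bit-identical.
    """
    relief = np.asarray(grid_data, dtype=np.float64)
    if seeds.n_seeds == 0:
        warnings.warn("empty seed set: returning an empty label volume")
        return LabelVolume(np.zeros(relief.shape, dtype=np.int32), 0)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if (seeds.seed_labels > 0)[~mask].any():
            raise ValueError("seeds must lie within the mask")
    conn = 3 if connectivity == 26 else 1
    labels = watershed(relief, markers=seeds.seed_labels, mask=mask, connectivity=conn)
    return LabelVolume.from_labels(labels)


# ---------------------------------------------------------------------------
# measurement and the full pipeline


def measure(labels: LabelVolume, grid: VoxelGrid) -> pd.DataFrame:
    """Per-cell table: centroid (µm), voxel count, volume, mean intensity.

    Centroids are intensity-unweighted (geometric centre of the region's
    voxel indices scaled by spacing); volume is voxels x dz*dy*dx exactly.
    """
    if labels.shape != grid.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs grid {grid.shape}")
    if labels.n_labels == 0:
        return make_cell_table()
    index = np.arange(1, labels.n_labels + 1)
    lab = labels.labels
    centroids = ndi.center_of_mass(np.ones(lab.shape), lab, index)
    counts = np.bincount(lab.ravel(), minlength=labels.n_labels + 1)[1:]
    means = ndi.mean(grid.data.astype(np.float64), lab, index)
    rows = []
    for i, label in enumerate(index):
        cz, cy, cx = centroids[i]
        rows.append(
            {
                "label": int(label),
                "centroid_z": cz * grid.dz,
                "centroid_y": cy * grid.dy,
                "centroid_x": cx * grid.dx,
                "voxels": int(counts[i]),
                "volume_um3": int(counts[i]) * grid.voxel_volume_um3,
                "mean_intensity": float(means[i]),
            }
        )
    return make_cell_table(rows)


def segment_dopa3d(
    grid: VoxelGrid, params: Dopa3DParams | None = None
) -> tuple[LabelVolume, pd.DataFrame]:
    """Run the full soma-segmentation pipeline on one stack.

    Returns the label volume and its cell table.  Deterministic: the same
    stack and parameters always give bit-identical output.
    """
    params = params or Dopa3DParams()
    denoised = median_filter_3d(grid, params.median_radius)
    closed = closing_3d(denoised, params.closing_radius)
    mask = closed.data >= params.dark_threshold
    suppressed = suppress_dark(closed, params.dark_threshold)
    if not mask.any():
        logger.info("no voxels above dark_threshold=%s: 0 cells", params.dark_threshold)
        empty = LabelVolume(np.zeros(grid.shape, dtype=np.int32), 0)
        return empty, make_cell_table()

    relief = suppressed.data.astype(np.float64)
    if params.invert:
        relief = relief.max() - relief

    flattened = hminima_transform(relief, params.h, params.connectivity)
    minima = regional_minima(flattened, params.connectivity) & mask
    seed_labels, _ = ndi.label(minima, structure=_structure(params.connectivity))
    if params.min_seed_voxels > 1:
        counts = np.bincount(seed_labels.ravel())
        small = counts < params.min_seed_voxels
        small[0] = False
        seed_labels[small[seed_labels]] = 0
    dense_seeds = LabelVolume.from_labels(seed_labels)
    seeds = SeedSet(dense_seeds.labels, dense_seeds.n_labels)
    if seeds.n_seeds == 0:
        empty = LabelVolume(np.zeros(grid.shape, dtype=np.int32), 0)
        return empty, make_cell_table()

    labels = watershed_3d(relief, seeds, mask=mask, connectivity=params.watershed_connectivity)
    return labels, measure(labels, grid)
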