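"""Post-segmentation plausibility filter for candidate cells.

Companion to the soma-segmentation pipeline: watershed fragments that are
too small, too large, too dim, or too far from spherical are struck from
the label volume before counting.  Defaults are permissive (volume bounds
only); intensity and sphericity bounds are opt-in because TH signal is
legitimately diffuse and irregular.

Sphericity uses the classic dimensionless ratio

    psi = pi^(1/3) * (6 V)^(2/3) / A

with V the region volume (µm³) and A the surface area estimated by
counting exposed voxel faces scaled by the voxel face areas.  psi = 1 for
a perfect sphere under an exact surface measure; digital balls score
lower (face counting overestimates A) but still well above sheets and
filaments, which is all the filter needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volio import LabelVolume, VoxelGrid, make_cell_table


@dataclass
class FilterCriteria:
    min_volume_um3: float = 20.0
    max_volume_um3: float = 2000.0
    min_mean_intensity: float | None = None
    min_sphericity: float | None = None

    def __post_init__(self) -> None:
        if self.min_volume_um3 > self.max_volume_um3:
            raise ValueError("min_volume_um3 must be <= max_volume_um3")
        if self.min_sphericity is not None and not (0 < self.min_sphericity <= 1):
            raise ValueError("min_sphericity must lie in (0, 1]")


def surface_area_um2(region: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Exposed-face surface area of a binary region, in µm².

    A face is exposed when a region voxel abuts a non-region voxel (or
    the volume border) along one of the six axis directions.  Face areas:
    z-faces dy*dx, y-faces dz*dx, x-faces dz*dy.
    """
    region = np.asarray(region, dtype=bool)
    dz, dy, dx = spacing
    face_area = (dy * dx, dz * dx, dz * dy)
    total = 0.0
    for axis in range(3):
        padded = np.pad(region, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        exposed = np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()
        total += float(exposed) * face_area[axis]
    return total


def sphericity(region: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """pi^(1/3)*(6V)^(2/3)/A on the exposed-face surface estimate."""
    region = np.asarray(region, dtype=bool)
    voxels = int(region.sum())
    if voxels == 0:
        return 0.0
    dz, dy, dx = spacing
    volume = voxels * dz * dy * dx
    area = surface_area_um2(region, spacing)
    return float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)


def filter_cells(
    labels: LabelVolume,
    table: pd.DataFrame,
    grid: VoxelGrid,
    criteria: FilterCriteria | None = None,
) -> tuple[LabelVolume, pd.DataFrame]:
    """Remove regions failing any criterion; re-densify survivors to 1..m.

    Surviving regions keep their voxels unchanged; the returned table is
    the input table filtered and relabelled consistently.  Idempotent.
    """
    criteria = criteria or FilterCriteria()
    if labels.shape != grid.shape:
        raise ValueError("labels and grid shapes differ")
    if len(table) != labels.n_labels or (
        labels.n_labels and not np.array_equal(
            np.sort(table["label"].to_numpy()), np.arange(1, labels.n_labels + 1)
        )
    ):
        raise ValueError("table rows do not match the label volume")

    keep: list[int] = []
    for row in table.sort_values("label").itertuples(index=False):
        if not (criteria.min_volume_um3 <= row.volume_um3 <= criteria.max_volume_um3):
            continue
        if (
            criteria.min_mean_intensity is not None
            and row.mean_intensity < criteria.min_mean_intensity
        ):
            continue
        if criteria.min_sphericity is not None:
            psi = sphericity(labels.labels == row.label, grid.spacing)
            if psi < criteria.min_sphericity:
                continue
        keep.append(int(row.label))

    lut = np.zeros(labels.n_labels + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    new_labels = LabelVolume(lut[labels.labels], n_labels=len(keep))

    if not keep:
        return new_labels, make_cell_table()
    kept = table[table["label"].isin(keep)].sort_values("label").copy()
    kept["label"] = lut[kept["label"].to_numpy()]
    return new_labels, kept.reset_index(drop=True)
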