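"""Seeded synthetic-data generators with exact ground truth.

Every pipeline stage in this package is testable without external data:
this module renders confocal-like stacks of bright somata (with known
labels and centroids), piecewise-constant-speed fly trajectories (with
analytically known locomotion metrics), and paired YFP/CFP frame series
(with known ratio courses).  All generators are pure functions of their
parameters and seed — identical inputs give bit-identical outputs.

The stack generator emulates the two signal regimes met in practice:
high-contrast near-spherical nuclear reporters, and dimmer, partially
touching soma clusters where pairs are bridged by an intensity neck.
Poisson noise is the default model because photon shot noise dominates
confocal acquisition.  No point-spread-function or photobleaching model
is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volio import LabelVolume, VoxelGrid, make_cell_table


class PackingError(RuntimeError):
    """Could not place the requested cells without forbidden overlap."""


@dataclass
class StackRecipe:
    """Recipe for one synthetic stack; fully determined by its seed.

    ``touching_fraction`` of the cells are laid out as fused pairs whose
    bridging neck dips to ``peak_intensity - neck_depth`` at its lowest
    point; the rest are singles kept at least ``separation_um`` apart.
    """

    shape: tuple[int, int, int] = (24, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 0.4, 0.4)
    n_cells: int = 20
    radius_um: tuple[float, float] = (2.0, 0.4)  # mean, sd
    peak_intensity: float = 200.0
    background: float = 10.0
    touching_fraction: float = 0.0
    neck_depth: float = 60.0
    noise: str = "poisson"  # "poisson" | "none"
    separation_um: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if not 0 <= self.touching_fraction <= 1:
            raise ValueError("touching_fraction must lie in [0, 1]")
        if self.peak_intensity - self.neck_depth <= self.background:
            raise ValueError("neck minimum would sink below background")


def pam_cluster_recipe(rng_seed: int = 0, **overrides) -> StackRecipe:
    """A PAM-cluster-like preset: ~110 somata, 15 % touching.

    Approximates one protocerebral-anterior-medial cluster per
    hemisphere; a convenience for demos and benchmarks, not a claim about
    any particular brain.
    """
    kwargs = dict(
        shape=(26, 220, 220),
        spacing=(1.0, 0.38, 0.38),
        n_cells=110,
        radius_um=(2.0, 0.4),
        touching_fraction=0.15,
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return StackRecipe(**kwargs)


def _core_and_sigma(r: float) -> tuple[float, float]:
    """Intensity profile scales for a soma of radius r.

    Somata are fluorophore-filled, so the profile has a flat bright core
    (radius r/2) with a Gaussian shoulder; sigma is set so the intensity
    at the nominal radius is exp(-1) of the amplitude.
    """
    core = r / 2.0
    sigma = core / np.sqrt(2.0)
    return core, sigma


def _profile(d: np.ndarray, r: float, amp: float) -> np.ndarray:
    core, sigma = _core_and_sigma(r)
    shoulder = np.maximum(d - core, 0.0)
    return amp * np.exp(-(shoulder**2) / (2.0 * sigma**2))


def _pair_distance_um(recipe: StackRecipe, r1: float, r2: float) -> float:
    """Centre distance making the max-of-profiles saddle equal
    peak - neck_depth."""
    amp = recipe.peak_intensity - recipe.background
    target = recipe.peak_intensity - recipe.neck_depth - recipe.background
    core, sigma = _core_and_sigma((r1 + r2) / 2.0)
    return float(2.0 * (core + sigma * np.sqrt(2.0 * np.log(amp / target))))


def make_cell_stack(recipe: StackRecipe) -> tuple[VoxelGrid, LabelVolume, pd.DataFrame]:
    """Render a stack of bright spheres; return (grid, truth labels, truth table).

    Each soma is rendered as a flat bright core (radius r/2) with a
    radial Gaussian shoulder on a uniform background, combined by
    pointwise max; touching pairs are placed close enough that the
    resulting neck bottoms out at peak - neck_depth.  Ground-truth
    labels assign each voxel within a sphere's radius to its (nearest)
    centre.
    """
    rng = np.random.default_rng(recipe.rng_seed)
    nz, ny, nx = recipe.shape
    dz, dy, dx = recipe.spacing
    extent = np.array([nz * dz, ny * dy, nx * dx])

    n_pairs = int(round(recipe.n_cells * recipe.touching_fraction / 2.0))
    n_singles = recipe.n_cells - 2 * n_pairs

    mean_r, sd_r = recipe.radius_um
    centers: list[np.ndarray] = []
    radii: list[float] = []

    def admissible(c: np.ndarray, r: float, ignore: set[int]) -> bool:
        if (c < r + 1.0).any() or (c > extent - r - 1.0).any():
            return False
        for j, (cj, rj) in enumerate(zip(centers, radii)):
            if j in ignore:
                continue
            if np.linalg.norm(c - cj) < r + rj + recipe.separation_um:
                return False
        return True

    def sample_radius() -> float:
        # clipped to the realistic soma range (diameter ~3-8 µm)
        return float(np.clip(rng.normal(mean_r, sd_r), 1.5, 4.0))

    pair_of: dict[int, int] = {}  # index -> partner index, for touching pairs

    for _ in range(n_pairs):
        # equal radii within a pair keep the neck minimum exactly at
        # peak - neck_depth (a larger partner would dominate the saddle)
        r1 = r2 = sample_radius()
        d = _pair_distance_um(recipe, r1, r2)
        for attempt in range(1000):
            c1 = rng.uniform(0, 1, 3) * extent
            # pair axis kept in-plane: at ~1 µm z-steps, two somata fused
            # along z are not resolvable, and clusters spread laterally
            theta = rng.uniform(0, 2 * np.pi)
            direction = np.array([0.0, np.sin(theta), np.cos(theta)])
            c2 = c1 + d * direction
            i1, i2 = len(centers), len(centers) + 1
            centers.extend([c1, c2])
            radii.extend([r1, r2])
            ok = admissible(c1, r1, {i1, i2}) and admissible(c2, r2, {i1, i2})
            if ok:
                pair_of[i1], pair_of[i2] = i2, i1
                break
            del centers[-2:], radii[-2:]
        else:
            raise PackingError(f"cannot place touching pair after 1000 attempts")

    for _ in range(n_singles):
        r = sample_radius()
        for attempt in range(1000):
            c = rng.uniform(0, 1, 3) * extent
            if admissible(c, r, set()):
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PackingError(
                f"cannot place {recipe.n_cells} cells in shape {recipe.shape}"
            )

    clean = np.full(recipe.shape, float(recipe.background))
    truth = np.zeros(recipe.shape, dtype=np.int32)
    # distance to the owning centre, for nearest-centre ties in overlaps
    owner_dist = np.full(recipe.shape, np.inf)
    amp = recipe.peak_intensity - recipe.background

    coords_um = (
        np.arange(nz)[:, None, None] * dz,
        np.arange(ny)[None, :, None] * dy,
        np.arange(nx)[None, None, :] * dx,
    )

    for i, (c, r) in enumerate(zip(centers, radii)):
        core, sigma = _core_and_sigma(r)
        reach = core + 3.0 * sigma + 1.0
        lo = np.maximum(0, np.floor((c - reach) / recipe.spacing).astype(int))
        hi = np.minimum(recipe.shape, np.ceil((c + reach) / recipe.spacing).astype(int) + 1)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        d2 = (
            (coords_um[0][sl[0], :, :] - c[0]) ** 2
            + (coords_um[1][:, sl[1], :] - c[1]) ** 2
            + (coords_um[2][:, :, sl[2]] - c[2]) ** 2
        )
        profile = recipe.background + _profile(np.sqrt(d2), r, amp)
        sub = clean[sl]
        np.maximum(sub, profile, out=sub)
        inside = d2 <= r**2
        closer = inside & (d2 < owner_dist[sl])
        truth[sl][closer] = i + 1
        owner_dist[sl][closer] = d2[closer]

    bit_depth = 8 if recipe.peak_intensity <= 255 else 16
    top = 2**bit_depth - 1
    if recipe.noise == "poisson":
        data = rng.poisson(clean).astype(np.float64)
    else:
        data = np.round(clean)
    data = np.clip(data, 0, top).astype(np.uint8 if bit_depth == 8 else np.uint16)

    grid = VoxelGrid(data, dz, dy, dx, bit_depth)
    labels = LabelVolume(truth, n_labels=len(centers))
    rows = []
    for i, (c, r) in enumerate(zip(centers, radii)):
        voxels = int((truth == i + 1).sum())
        rows.append(
            {
                "label": i + 1,
                "centroid_z": c[0],
                "centroid_y": c[1],
                "centroid_x": c[2],
                "voxels": voxels,
                "volume_um3": voxels * dz * dy * dx,
                "mean_intensity": float(recipe.peak_intensity),
            }
        )
    return grid, labels, make_cell_table(rows)


# ---------------------------------------------------------------------------
# trajectories


def make_trajectories(
    n_flies: int,
    duration_s: float,
    fps: float = 25.0,
    mm_per_px: float = 0.1,
    bout_speeds: list[tuple[float, float]] | None = None,
    rng_seed: int = 0,
    arena_radius_mm: float = 12.0,
    walk_threshold_mm_s: float = 4.0,
    immobility_threshold_mm_s: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-heading walks with piecewise-constant speed in a round arena.

    ``bout_speeds`` is a list of (speed mm/s, fraction of time) pairs
    whose fractions sum to 1; each fly follows the bouts in order.  The
    step length is exact per frame, so locomotion metrics have closed
    forms, returned in the truth table (walking_distance_mm,
    walking_speed_mm_s — NaN when no frame exceeds the walk threshold —
    and time_immobile_s).

    Returns (trajectory table with columns frame, fly, x, y in pixels,
    plus fps/mm_per_px in ``attrs``; truth table per fly).
    """
    bout_speeds = bout_speeds or [(8.0, 0.6), (0.0, 0.4)]
    fracs = np.array([f for _, f in bout_speeds], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("bout fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    n_steps = int(round(duration_s * fps))
    edges = np.round(np.cumsum(fracs) * n_steps).astype(int)
    counts = np.diff(np.concatenate([[0], edges]))
    step_speeds = np.repeat([s for s, _ in bout_speeds], counts)  # mm/s per interval

    radius_px = arena_radius_mm / mm_per_px
    rows = []
    truth_rows = []
    for fly in range(n_flies):
        pos = rng.uniform(-0.5, 0.5, 2) * radius_px
        track = [pos.copy()]
        for s in step_speeds:
            step_px = (s / fps) / mm_per_px
            for _ in range(64):
                theta = rng.uniform(0, 2 * np.pi)
                cand = pos + step_px * np.array([np.cos(theta), np.sin(theta)])
                if np.linalg.norm(cand) <= radius_px:
                    break
            else:  # hug the wall: step straight back toward the centre
                cand = pos - step_px * pos / max(np.linalg.norm(pos), 1e-9)
            pos = cand
            track.append(pos.copy())
        for frame, (x, y) in enumerate(track):
            rows.append({"frame": frame, "fly": fly, "x": x, "y": y})

        walking = step_speeds[step_speeds > walk_threshold_mm_s]
        truth_rows.append(
            {
                "fly": fly,
                "walking_distance_mm": float(step_speeds.sum() / fps),
                "walking_speed_mm_s": float(walking.mean()) if len(walking) else np.nan,
                "time_immobile_s": float(
                    (step_speeds < immobility_threshold_mm_s).sum() / fps
                ),
            }
        )

    traj = pd.DataFrame(rows)
    traj.attrs["fps"] = fps
    traj.attrs["mm_per_px"] = mm_per_px
    return traj, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# FRET frame pairs


def make_fret_series(
    ratio_course: list[float] | np.ndarray,
    n_timepoints: int = 11,
    roi_shape: tuple[int, int] = (32, 32),
    noise_sd: float = 0.0,
    cfp_level: float = 100.0,
    rng_seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Paired YFP/CFP frames with a known YFP/CFP ratio course.

    Emulates the cAMP-sensor acquisition schedule (one pre-stimulation
    frame then repeated cycles, 11 time points by default).  CFP frames
    are constant at ``cfp_level``; YFP = ratio x CFP + Gaussian noise.

    Returns (yfp frames, cfp frames, true ratios).
    """
    ratios = np.asarray(ratio_course, dtype=float)
    if len(ratios) != n_timepoints:
        raise ValueError(
            f"ratio_course has {len(ratios)} values but n_timepoints={n_timepoints}"
        )
    rng = np.random.default_rng(rng_seed)
    cfp = [np.full(roi_shape, cfp_level) for _ in range(n_timepoints)]
    yfp = [
        np.clip(r * cfp_level + rng.normal(0.0, noise_sd, roi_shape), 0.0, None)
        if noise_sd > 0
        else np.full(roi_shape, r * cfp_level)
        for r in ratios
    ]
    return yfp, cfp, ratios
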