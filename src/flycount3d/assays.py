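"""Behavioural and molecular assay quantification.

The formulas implemented here are the standard fly-lab readouts:

* climbing performance index for startle-induced negative geotaxis,
  PI = 1/2 * (ntot + ntop - nbot) / ntot, in [0, 1];
* open-arena locomotion metrics from tracker trajectories — walking
  distance (sum of all per-frame displacements), walking speed (mean
  speed over frames strictly above the walk threshold, 4 mm/s by
  default, about two body lengths per second), and time immobile
  (frames below the immobility threshold, 1 mm/s by default);
* appetitive-memory performance index, averaged over the reciprocal
  odour pairing, with groups of fewer than 15 scored flies discarded;
* ratiometric FRET YFP/CFP time series (per-pixel ratio, ROI mean, one
  value per time point — 11 for the standard stimulate-every-30-s
  schedule), the readout of the Epac1 cAMP sensor;
* relative gene expression by the Livak 2^-ddCt method.

Group-level hypothesis testing is deliberately out of scope; these
functions emit tidy per-trial / per-fly / per-sample numbers for
standard statistics tooling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClimbingTrial:
    """One negative-geotaxis trial: total flies, flies above the top
    line, flies below the bottom line."""

    ntot: int
    ntop: int
    nbot: int

    def __post_init__(self) -> None:
        if self.ntot <= 0:
            raise ValueError("ntot must be positive")
        if min(self.ntop, self.nbot) < 0:
            raise ValueError("counts must be non-negative")
        if self.ntop + self.nbot > self.ntot:
            raise ValueError("ntop + nbot cannot exceed ntot")


def climbing_pi(trial: ClimbingTrial) -> float:
    """PI = 1/2 * (ntot + ntop - nbot) / ntot.

    1 when every fly reaches the top, 0 when every fly stays at the
    bottom, 1/2 whenever top and bottom counts balance.
    """
    return 0.5 * (trial.ntot + trial.ntop - trial.nbot) / trial.ntot


@dataclass
class LocomotionParams:
    """Thresholds for the open-arena metrics (mm/s).

    The walk threshold follows the two-body-lengths convention (4 mm/s);
    the immobility cutoff has no single standard and defaults to
    1 mm/s — roughly half a body length per second — and is flagged in
    output metadata so reports can state it.
    """

    walk_threshold_mm_s: float = 4.0
    immobility_threshold_mm_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.immobility_threshold_mm_s <= self.walk_threshold_mm_s:
            raise ValueError("need 0 <= immobility threshold <= walk threshold")


def locomotion_metrics(
    traj: pd.DataFrame,
    params: LocomotionParams | None = None,
    fps: float | None = None,
    mm_per_px: float | None = None,
) -> pd.DataFrame:
    """Per-fly walking distance, walking speed, and time immobile.

    ``traj`` needs columns frame, fly, x, y (pixels); fps and mm_per_px
    are read from ``traj.attrs`` unless passed explicitly.  Per-frame
    speed is the Euclidean displacement between consecutive frames times
    mm_per_px times fps.  Walking distance sums ALL displacements;
    walking speed averages only frames strictly above the walk
    threshold and is NaN when no frame qualifies.
    """
    params = params or LocomotionParams()
    fps = fps if fps is not None else traj.attrs.get("fps")
    mm_per_px = mm_per_px if mm_per_px is not None else traj.attrs.get("mm_per_px")
    if not fps or fps <= 0 or not mm_per_px or mm_per_px <= 0:
        raise ValueError("fps and mm_per_px must be provided and positive")

    rows = []
    for fly, g in traj.sort_values(["fly", "frame"]).groupby("fly", sort=True):
        if len(g) < 2:
            raise ValueError(f"fly {fly} has fewer than 2 frames")
        xy = g[["x", "y"]].to_numpy(dtype=float)
        disp_mm = np.linalg.norm(np.diff(xy, axis=0), axis=1) * mm_per_px
        speed = disp_mm * fps
        walking = speed[speed > params.walk_threshold_mm_s]
        rows.append(
            {
                "fly": fly,
                "walking_distance_mm": float(disp_mm.sum()),
                "walking_speed_mm_s": float(walking.mean()) if len(walking) else np.nan,
                "time_immobile_s": float(
                    (speed < params.immobility_threshold_mm_s).sum() / fps
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["walk_threshold_mm_s"] = params.walk_threshold_mm_s
    out.attrs["immobility_threshold_mm_s"] = params.immobility_threshold_mm_s
    return out


@dataclass
class ConditioningTest:
    """One half of a reciprocal appetitive-conditioning test."""

    n_cs_plus: int
    n_cs_minus: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if min(self.n_cs_plus, self.n_cs_minus) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_cs_plus + self.n_cs_minus > self.n_total:
            raise ValueError("odorant counts cannot exceed n_total")


MIN_SCORED_FLIES = 15  # halves with fewer flies among both odorants are discarded


def memory_pi(half_a: ConditioningTest, half_b: ConditioningTest) -> float | None:
    """Single memory PI from a reciprocal pair of conditioning tests.

    Each half scores (approaches to CS+ minus approaches to CS-) over
    total flies; a half with fewer than 15 flies among both odorants is
    discarded, and the single PI (the mean of the halves) is then
    undefined — returned as None.
    """
    pis = []
    for half in (half_a, half_b):
        if half.n_cs_plus + half.n_cs_minus < MIN_SCORED_FLIES:
            return None
        pis.append((half.n_cs_plus - half.n_cs_minus) / half.n_total)
    return float(np.mean(pis))


def fret_ratio_series(
    yfp: list[np.ndarray],
    cfp: list[np.ndarray],
    roi: np.ndarray,
    cfp_floor: float = 1.0,
) -> np.ndarray:
    """Mean per-pixel YFP/CFP ratio in the ROI, one value per time point.

    For each time point the YFP frame is divided pixel-wise by the CFP
    frame; the mean is taken over ROI pixels whose CFP signal is at
    least ``cfp_floor`` (pixels below it carry no usable denominator and
    are excluded).  A lower ratio means less FRET, i.e. more cAMP bound
    to the sensor.
    """
    if len(yfp) != len(cfp):
        raise ValueError("YFP and CFP series must have the same length")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    ratios = np.empty(len(yfp))
    for t, (y, c) in enumerate(zip(yfp, cfp)):
        y = np.asarray(y, dtype=float)
        c = np.asarray(c, dtype=float)
        if y.shape != roi.shape or c.shape != roi.shape:
            raise ValueError(f"frame {t}: shape mismatch with ROI")
        valid = roi & (c >= cfp_floor)
        if not valid.any():
            raise ValueError(f"time point {t}: all ROI pixels below the CFP floor")
        ratios[t] = (y[valid] / c[valid]).mean()
    return ratios


def ddct_fold_change(table: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Relative expression 2^-ddCt per sample (Livak method).

    ``table`` needs columns sample, group, ct_target, ct_reference (a
    replicate column is optional; technical replicates are averaged per
    sample first).  dCt = ct_target - ct_reference per sample; the
    baseline is the mean dCt over control-group samples, so the
    geometric mean of control fold changes is exactly 1.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    per_sample = (
        table.groupby(["sample", "group"], sort=False)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    per_sample["delta_ct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    controls = per_sample[per_sample["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    baseline = controls["delta_ct"].mean()
    per_sample["delta_delta_ct"] = per_sample["delta_ct"] - baseline
    per_sample["fold_change"] = 2.0 ** (-per_sample["delta_delta_ct"])
    return per_sample
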