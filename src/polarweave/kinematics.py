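"""Trajectory-level measures of intercellular positional stability.

Relative motility: trajectories are registered so that a chosen anchor
cell stays stationary; each other cell's path length per hour then
measures how much it rearranges relative to its neighbourhood
(Σ d_n / hour over the analysis window). In a perfectly solid sheet it
is zero.

Pair diffusion: for cell pairs that start close together (within ~23 μm),
the mean squared inter-pair distance is followed over time; its linear
slope distinguishes a solid sheet (slope ≈ 0, separations frozen) from a
fluidised one (positive slope, neighbours diffuse apart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .synth import TrajectoryTable


@dataclass
class PairDiffusionResult:
    lags_h: np.ndarray
    mean_sq_separation_um2: np.ndarray
    slope_um2_per_h: float
    intercept_um2: float
    n_pairs: int


def _positions_over_window(table: TrajectoryTable,
                           frames: np.ndarray) -> dict[int, np.ndarray]:
    """track_id -> (n_frames, 2) positions, only tracks complete over frames."""
    out: dict[int, np.ndarray] = {}
    for tid, grp in table.data.groupby("track_id"):
        sub = grp.set_index("frame").reindex(frames)
        if sub[["x_um", "y_um"]].isna().any().any():
            continue
        out[int(tid)] = sub[["x_um", "y_um"]].to_numpy()
    return out


def relative_motility(table: TrajectoryTable, anchor_id: int,
                      window_frames: int = 101,
                      start_frame: int | None = None) -> pd.Series:
    """Per-track path length per hour after anchor registration (μm/h).

    Every frame is translated so the anchor cell is stationary; per
    non-anchor track present in all frames of the window, the per-frame
    Euclidean step lengths are summed and divided by the window duration
    in hours ((window_frames − 1) · frame interval).
    """
    anchor = table.data[table.data["track_id"] == anchor_id]
    if anchor.empty:
        raise ValueError(f"anchor track {anchor_id} not found")
    f0 = int(anchor["frame"].min()) if start_frame is None else start_frame
    frames = np.arange(f0, f0 + window_frames)
    missing = sorted(set(frames) - set(anchor["frame"].tolist()))
    if missing:
        raise ValueError(f"anchor track {anchor_id} missing frames {missing}")
    pos = _positions_over_window(table, frames)
    anchor_pos = pos.pop(anchor_id)
    shift = anchor_pos - anchor_pos[0]     # anchor displacement per frame
    duration_h = (window_frames - 1) * table.frame_interval_h
    out = {}
    for tid, p in pos.items():
        reg = p - shift
        steps = np.hypot(*np.diff(reg, axis=0).T)
        out[tid] = steps.sum() / duration_h
    return pd.Series(out, name="relative_motility_umph").sort_index()


def pair_msd(table: TrajectoryTable, initial_radius: float = 23.0,
             window_frames: int | None = None,
             start_frame: int | None = None,
             min_pairs: int = 30) -> PairDiffusionResult:
    """Mean squared inter-pair distance vs time, and its OLS slope (μm²/h).

    Pairs are tracks within ``initial_radius`` of each other at the first
    frame of the window, both complete over the window. Fewer than
    ``min_pairs`` qualifying pairs triggers a warning (the count is
    reported); zero is an error.
    """
    all_frames = np.sort(table.data["frame"].unique())
    f0 = int(all_frames[0]) if start_frame is None else start_frame
    n = len(all_frames) if window_frames is None else window_frames
    frames = np.arange(f0, f0 + n)
    pos = _positions_over_window(table, frames)
    ids = sorted(pos)
    qual = [(a, b) for a, b in combinations(ids, 2)
            if np.hypot(*(pos[a][0] - pos[b][0])) <= initial_radius]
    if not qual:
        raise ValueError("no qualifying track pairs within the initial radius")
    if len(qual) < min_pairs:
        warnings.warn(f"only {len(qual)} qualifying pairs (< {min_pairs})",
                      stacklevel=2)
    sq = np.zeros((len(qual), len(frames)))
    for k, (a, b) in enumerate(qual):
        diff = pos[a] - pos[b]
        sq[k] = diff[:, 0]**2 + diff[:, 1]**2
    msd = sq.mean(axis=0)
    lags_h = (frames - frames[0]) * table.frame_interval_h
    slope, intercept = np.polyfit(lags_h, msd, 1)
    return PairDiffusionResult(lags_h=lags_h, mean_sq_separation_um2=msd,
                               slope_um2_per_h=float(slope),
                               intercept_um2=float(intercept),
                               n_pairs=len(qual))
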