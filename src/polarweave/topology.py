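"""±1 topological defect detection on gridded velocity fields.

The winding number at grid point (i, j) is the net rotation, in units of
2π, of the velocity direction along the anticlockwise loop of its eight
neighbours (starting at the top-left neighbour):

    θ_k = atan2(v_k, u_k)
    α_k = θ_k + 2π if θ_k < 0 else θ_k
    Δ_k = α_k − α_{k−1}   (Δ_1 = α_1 − α_8)
    δ_k = Δ_k ± 2π folded into (−π, π]
    ω   = round(Σ_k δ_k / 2π)

ω = +1 marks a vortex (counterclockwise or clockwise spin), ω = −1 a
saddle (antivortex). Raw detections are cleaned by two filters: grid
points of the same charge closer than a merge radius (default 165 μm)
are collapsed into one defect at their centroid, and defects must
persist for at least two consecutive frames to be kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synth import VelocityFieldFrame


@dataclass(frozen=True)
class DetectionParams:
    merge_radius: float = 165.0          # μm, same-charge single-linkage
    min_persistence_frames: int = 2
    link_radius: float | None = None     # μm; default = merge_radius

    def __post_init__(self) -> None:
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be positive")
        if self.min_persistence_frames < 1:
            raise ValueError("min_persistence_frames must be >= 1")

    @property
    def persistence_link_radius(self) -> float:
        return self.merge_radius if self.link_radius is None else self.link_radius


@dataclass
class DefectRecord:
    frame: int
    position: np.ndarray     # (2,) μm
    charge: int              # ±1 typically; larger |ω| reported verbatim
    cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("defect charge cannot be 0")


@dataclass
class DefectSet:
    frame: int
    time: float
    records: list[DefectRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, charge: int | None = None) -> np.ndarray:
        recs = [r for r in self.records
                if charge is None or r.charge == charge]
        if not recs:
            return np.empty((0, 2))
        return np.array([r.position for r in recs])

    def count(self, charge: int) -> int:
        return sum(1 for r in self.records if r.charge == charge)


# Eight neighbours of (ix, iy), anticlockwise from the top-left, in
# mathematical axes (y up): angular positions 135°,180°,225°,270°,315°,0°,45°,90°.
_NEIGHBOR_OFFSETS = [(-1, 1), (-1, 0), (-1, -1), (0, -1),
                     (1, -1), (1, 0), (1, 1), (0, 1)]  # (dix, diy)


def _fold(delta: np.ndarray) -> np.ndarray:
    """Range-adjust direction differences into (−π, π]."""
    out = np.where(delta < -np.pi, delta + 2 * np.pi, delta)
    return np.where(out > np.pi, out - 2 * np.pi, out)


def winding_number(frame: VelocityFieldFrame, ix: int, iy: int) -> int | None:
    """Winding number at one grid point; None if any neighbour is invalid."""
    ny, nx = frame.shape
    if not (1 <= ix < nx - 1 and 1 <= iy < ny - 1):
        return None
    valid = frame.valid()
    alphas = []
    for dix, diy in _NEIGHBOR_OFFSETS:
        jx, jy = ix + dix, iy + diy
        if not valid[jy, jx]:
            return None
        theta = np.arctan2(frame.v[jy, jx], frame.u[jy, jx])
        alphas.append(theta + 2 * np.pi if theta < 0 else theta)
    alphas = np.asarray(alphas)
    delta = _fold(alphas - np.roll(alphas, 1))
    return int(np.rint(delta.sum() / (2 * np.pi)))


def winding_map(frame: VelocityFieldFrame) -> np.ndarray:
    """Winding number at every interior grid point (vectorised).

    Points with any invalid neighbour get 0. Equivalent to calling
    :func:`winding_number` at each point.
    """
    theta = frame.direction()
    alpha = np.where(theta < 0, theta + 2 * np.pi, theta)
    valid = frame.valid()
    core = np.s_[1:-1, 1:-1]
    stack = []
    ok = np.ones(alpha[core].shape, dtype=bool)
    for dix, diy in _NEIGHBOR_OFFSETS:
        sl = np.s_[1 + diy:alpha.shape[0] - 1 + diy,
                   1 + dix:alpha.shape[1] - 1 + dix]
        stack.append(alpha[sl])
        ok &= valid[sl]
    stack = np.stack(stack)                      # (8, Ny-2, Nx-2)
    delta = _fold(stack - np.roll(stack, 1, axis=0))
    w = np.rint(delta.sum(axis=0) / (2 * np.pi)).astype(int)
    w[~ok] = 0
    out = np.zeros(frame.shape, dtype=int)
    out[core] = w
    return out


def _single_linkage_clusters(points: np.ndarray, radius: float,
                             strict: bool = False) -> list[list[int]]:
    """Union-find single-linkage clustering at the given radius.

    ``strict`` links only pairs strictly closer than the radius
    ("closer than" semantics); otherwise pairs at exactly the radius
    link too.
    """
    n = len(points)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(points)
    for a, b in tree.query_pairs(radius):
        if strict and np.hypot(*(points[a] - points[b])) >= radius:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)
    return list(groups.values())


def detect_frame(frame: VelocityFieldFrame, params: DetectionParams,
                 frame_index: int = 0) -> DefectSet:
    """All merged defect records in one frame.

    A defect core straddles a grid cell, so the winding fires on the
    handful of adjacent nodes whose 8-loops enclose it; those contiguous
    nodes (single-linkage at 1.5 grid spacings, same charge) are first
    collapsed into one core at their centroid. Cores of the same charge
    strictly closer than ``merge_radius`` are then merged into a single
    defect (size-weighted centroid). Opposite charges are never merged —
    that would erase imminent annihilation pairs.
    """
    w = winding_map(frame)
    X, Y = np.meshgrid(frame.x, frame.y)
    records: list[DefectRecord] = []
    for charge in sorted(np.unique(w[w != 0])):
        sel = w == charge
        pts = np.column_stack([X[sel], Y[sel]])
        # stage 1: contiguous winding nodes -> one localized core
        cores = []
        sizes = []
        for grp in _single_linkage_clusters(pts, 1.5 * frame.spacing):
            cores.append(pts[grp].mean(axis=0))
            sizes.append(len(grp))
        cores = np.asarray(cores)
        sizes = np.asarray(sizes)
        # stage 2: merge cores strictly closer than the merge radius
        for grp in _single_linkage_clusters(cores, params.merge_radius,
                                            strict=True):
            wts = sizes[grp] / sizes[grp].sum()
            centroid = (cores[grp] * wts[:, None]).sum(axis=0)
            records.append(DefectRecord(frame=frame_index, position=centroid,
                                        charge=int(charge),
                                        cluster_size=int(sizes[grp].sum())))
    return DefectSet(frame=frame_index, time=frame.time, records=records)


def detect_series(frames: list[VelocityFieldFrame],
                  params: DetectionParams) -> list[DefectSet]:
    return [detect_frame(f, params, frame_index=k)
            for k, f in enumerate(frames)]


def filter_persistent(sets: list[DefectSet],
                      params: DetectionParams) -> list[DefectSet]:
    """Keep only defects present in >= min_persistence_frames consecutive frames.

    A record in frame t matches a same-charge record in frame t±1 within
    the persistence link radius; the length of the maximal consecutive
    chain through a record must reach the threshold.
    """
    p = params.min_persistence_frames
    if p <= 1:
        return sets
    radius = params.persistence_link_radius
    n = len(sets)
    # forward chain length via nearest same-charge match in the next frame
    fwd = [np.ones(len(s), dtype=int) for s in sets]
    bwd = [np.ones(len(s), dtype=int) for s in sets]

    def _match(src: DefectSet, dst: DefectSet) -> list[int | None]:
        out: list[int | None] = [None] * len(src)
        if not len(src) or not len(dst):
            return out
        dpos = np.array([r.position for r in dst.records])
        dch = np.array([r.charge for r in dst.records])
        tree = cKDTree(dpos)
        for k, rec in enumerate(src.records):
            dist, idx = tree.query(rec.position,
                                   k=min(len(dst), 8),
                                   distance_upper_bound=radius)
            for dd, ii in zip(np.atleast_1d(dist), np.atleast_1d(idx)):
                if np.isfinite(dd) and dch[ii] == rec.charge:
                    out[k] = int(ii)
                    break
        return out

    for t in range(n - 2, -1, -1):
        m = _match(sets[t], sets[t + 1])
        for k, j in enumerate(m):
            if j is not None:
                fwd[t][k] = 1 + fwd[t + 1][j]
    for t in range(1, n):
        m = _match(sets[t], sets[t - 1])
        for k, j in enumerate(m):
            if j is not None:
                bwd[t][k] = 1 + bwd[t - 1][j]

    out_sets = []
    for t, s in enumerate(sets):
        kept = [r for k, r in enumerate(s.records)
                if fwd[t][k] + bwd[t][k] - 1 >= p]
        out_sets.append(DefectSet(frame=s.frame, time=s.time, records=kept))
    return out_sets


def density_series(sets: list[DefectSet], domain_area_um2: float) -> pd.DataFrame:
    """Counts N₊(t), N₋(t) and densities per mm² for each frame."""
    if domain_area_um2 <= 0:
        raise ValueError("domain area must be positive")
    area_mm2 = domain_area_um2 / 1e6
    rows = []
    for s in sets:
        n_plus = s.count(+1)
        n_minus = s.count(-1)
        rows.append({"frame": s.frame, "t_h": s.time,
                     "n_plus": n_plus, "n_minus": n_minus,
                     "n_total": len(s),
                     "density_plus_per_mm2": n_plus / area_mm2,
                     "density_minus_per_mm2": n_minus / area_mm2})
    return pd.DataFrame(rows)


def loop_winding(frame: VelocityFieldFrame, ix0: int, ix1: int,
                 iy0: int, iy1: int) -> int:
    """Winding of the field along the boundary of a grid rectangle.

    Brute-force oracle: sums folded direction differences anticlockwise
    along the rectangle [ix0, ix1] × [iy0, iy1]; equals the total charge
    enclosed.
    """
    theta = frame.direction()
    path = []
    for ix in range(ix0, ix1):
        path.append(theta[iy0, ix])
    for iy in range(iy0, iy1):
        path.append(theta[iy, ix1])
    for ix in range(ix1, ix0, -1):
        path.append(theta[iy1, ix])
    for iy in range(iy1, iy0, -1):
        path.append(theta[iy, ix0])
    path = np.asarray(path)
    delta = _fold(np.roll(path, -1) - path)
    return int(np.rint(delta.sum() / (2 * np.pi)))
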