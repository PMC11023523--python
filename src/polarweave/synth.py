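"""Synthetic gridded velocity fields and trajectory tables with known truth.

These generators emulate the output of PIV on a migrating monolayer —
a regular grid of (u, v) vectors — with fully controlled ground truth:
planted ±1 defects with chosen spin, direction noise with a prescribed
spatial correlation length, and cell-trajectory tables in rigid,
diffusive, or mixed relative-motion regimes. Every analysis stage can
therefore be validated against quantities that are known exactly.

Grid convention: mathematical axes (x right, y up), arrays indexed
``[iy, ix]`` with both coordinates ascending. A counterclockwise vortex
has winding number +1 under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class VelocityFieldFrame:
    """One PIV-like frame: (u, v) on a regular grid, μm and μm/h."""

    x: np.ndarray            # (Nx,) node x coordinates, ascending
    y: np.ndarray            # (Ny,) node y coordinates, ascending
    u: np.ndarray            # (Ny, Nx)
    v: np.ndarray            # (Ny, Nx)
    time: float = 0.0        # h
    mask: np.ndarray | None = None   # (Ny, Nx) True where valid

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) < 3 or len(self.y) < 3:
            raise ValueError("grid must be at least 3x3")
        if self.u.shape != (len(self.y), len(self.x)):
            raise ValueError("u shape does not match grid")
        if self.v.shape != self.u.shape:
            raise ValueError("u and v shapes differ")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def valid(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.u.shape, dtype=bool)
        return self.mask

    def direction(self) -> np.ndarray:
        """θ(x, y) = atan2(v, u)."""
        return np.arctan2(self.v, self.u)

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


FieldSeries = list  # list[VelocityFieldFrame]


@dataclass(frozen=True)
class DefectSpec:
    """A planted point defect: position, charge and spin phase ψ.

    For charge +1, ψ = +π/2 gives a counterclockwise vortex, −π/2 a
    clockwise one, 0 an aster (outflow); for charge −1, ψ rotates the
    saddle axes.
    """

    center: tuple[float, float]
    charge: int
    psi: float = np.pi / 2

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("defect charge must be +1 or -1")


def make_grid(extent: float, n: int, origin: float = 0.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Square n×n grid of coordinates covering [origin, origin+extent]."""
    x = origin + np.linspace(0.0, extent, n)
    return x, x.copy()


def compose_defect_field(defects: list[DefectSpec], x: np.ndarray,
                         y: np.ndarray, speed: float = 35.0,
                         time: float = 0.0) -> VelocityFieldFrame:
    """Superpose point defects into a unit-speed direction field.

    θ(x, y) = Σ_k q_k · atan2(y − y_k, x − x_k) + Σ_k ψ_k, the standard
    angle-superposition construction: the winding number around each
    centre equals its charge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    centers = np.array([d.center for d in defects], dtype=float).reshape(-1, 2)
    if len(centers) >= 2:
        dists = np.hypot(*(centers[:, None, :] - centers[None, :, :]
                           ).transpose(2, 0, 1))
        np.fill_diagonal(dists, np.inf)
        spacing = float(x[1] - x[0])
        if dists.min() <= 0:
            raise ValueError("coincident defect centers")
        if dists.min() < 2 * spacing:
            raise ValueError("defect centers closer than 2 grid spacings")
    for cx, cy in centers:
        if not (x[0] <= cx <= x[-1] and y[0] <= cy <= y[-1]):
            raise ValueError(f"defect center ({cx}, {cy}) outside grid")
    X, Y = np.meshgrid(x, y)
    theta = np.zeros_like(X)
    for dspec in defects:
        cx, cy = dspec.center
        theta += dspec.charge * np.arctan2(Y - cy, X - cx) + dspec.psi
    return VelocityFieldFrame(x=x, y=y, u=speed * np.cos(theta),
                              v=speed * np.sin(theta), time=time)


def correlated_noise_field(lambda_corr: float, x: np.ndarray, y: np.ndarray,
                           seed: int, speed: float = 35.0,
                           sigma_theta: float = 0.4,
                           mean_direction: float = 0.0,
                           time: float = 0.0) -> VelocityFieldFrame:
    """Direction field with exponentially correlated Gaussian perturbations.

    The direction is θ = mean_direction + δθ(x, y) where δθ is a zero-mean
    Gaussian field with autocorrelation ≈ exp(−r/λ), built by circulant
    spectral filtering on a 2× padded grid (exact target correlation on
    the torus, O(N log N)).
    """
    if lambda_corr <= 0:
        raise ValueError("lambda_corr must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    spacing = float(x[1] - x[0])
    rng = np.random.default_rng(seed)
    # padded torus grid to kill wrap-around correlation in the crop
    px, py = 2 * nx, 2 * ny
    fx = np.minimum(np.arange(px), px - np.arange(px)) * spacing
    fy = np.minimum(np.arange(py), py - np.arange(py)) * spacing
    rr = np.hypot(fx[None, :], fy[:, None])
    cov = np.exp(-rr / lambda_corr)
    spec = np.fft.fft2(cov).real
    spec[spec < 0] = 0.0
    white = rng.standard_normal((py, px))
    fld = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(white)).real
    fld = fld[:ny, :nx]
    sd = fld.std()
    if sd > 0:
        fld *= sigma_theta / sd
    theta = mean_direction + fld
    return VelocityFieldFrame(x=x, y=y, u=speed * np.cos(theta),
                              v=speed * np.sin(theta), time=time)


def grid_particle_velocities(positions: np.ndarray, velocities: np.ndarray,
                             grid_spacing: float = 66.0,
                             window: float = 165.0,
                             extent: tuple[float, float, float, float] | None = None,
                             time: float = 0.0) -> VelocityFieldFrame:
    """Sample particle velocities onto a PIV-like grid.

    Each node's (u, v) is the mean velocity of all particles inside the
    centred square window of side ``window``; with the default 66-μm step
    and 165-μm window, neighbouring windows overlap by 99 μm. Nodes with
    empty windows are masked invalid.
    """
    positions = np.asarray(positions, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if extent is None:
        xmin, ymin = positions.min(axis=0)
        xmax, ymax = positions.max(axis=0)
    else:
        xmin, xmax, ymin, ymax = extent
    nx = max(int(np.floor((xmax - xmin) / grid_spacing)) + 1, 3)
    ny = max(int(np.floor((ymax - ymin) / grid_spacing)) + 1, 3)
    x = xmin + grid_spacing * np.arange(nx)
    y = ymin + grid_spacing * np.arange(ny)
    X, Y = np.meshgrid(x, y)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    tree = cKDTree(positions)
    # Chebyshev ball of radius window/2 == centred square window
    hits = tree.query_ball_point(nodes, r=window / 2.0, p=np.inf)
    u = np.zeros(nx * ny)
    v = np.zeros(nx * ny)
    mask = np.zeros(nx * ny, dtype=bool)
    for k, idx in enumerate(hits):
        if idx:
            u[k] = velocities[idx, 0].mean()
            v[k] = velocities[idx, 1].mean()
            mask[k] = True
    if not mask.any():
        raise ValueError("no particles fall in any interrogation window")
    return VelocityFieldFrame(x=x, y=y, u=u.reshape(ny, nx),
                              v=v.reshape(ny, nx), time=time,
                              mask=mask.reshape(ny, nx))


@dataclass
class TrajectoryTable:
    """Labelled point tracks with frame-interval metadata.

    ``data`` columns: track_id, frame, x_um, y_um.
    """

    data: pd.DataFrame
    frame_interval_h: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"track_id", "frame", "x_um", "y_um"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        for tid, grp in self.data.groupby("track_id"):
            f = grp["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                raise ValueError(f"track {tid}: frames not strictly increasing")
        if not np.isfinite(self.data[["x_um", "y_um"]].to_numpy()).all():
            raise ValueError("non-finite positions in trajectory table")


def synth_trajectories(regime: str, n_cells: int, n_frames: int,
                       frame_interval: float, seed: int,
                       step_std: float = 1.0, drift_std: float = 2.0,
                       spread: float = 100.0) -> TrajectoryTable:
    """Trajectory fixtures with known relative-motion ground truth.

    regime "rigid": all tracks share one random-walk displacement series
    (zero relative motion); "diffusive": independent 2D Gaussian walks
    with per-frame, per-axis step std ``step_std``; "mixed": shared drift
    plus independent walks. Initial positions uniform in a
    ``spread``-sized square. Track 0 starts at the centre (anchor).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    start = rng.uniform(-spread / 2, spread / 2, size=(n_cells, 2))
    start[0] = 0.0
    drift_steps = rng.normal(scale=drift_std, size=(n_frames - 1, 2))
    indiv = rng.normal(scale=step_std, size=(n_frames - 1, n_cells, 2))
    if regime == "rigid":
        steps = np.broadcast_to(drift_steps[:, None, :],
                                (n_frames - 1, n_cells, 2))
    elif regime == "diffusive":
        steps = indiv
    elif regime == "mixed":
        steps = drift_steps[:, None, :] + indiv
    else:
        raise ValueError(f"unknown regime {regime!r}")
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    frames = np.arange(n_frames)
    df = pd.DataFrame({
        "track_id": np.repeat(np.arange(n_cells), n_frames),
        "frame": np.tile(frames, n_cells),
        "x_um": pos[:, :, 0].T.ravel(),
        "y_um": pos[:, :, 1].T.ravel(),
    })
    return TrajectoryTable(data=df, frame_interval_h=frame_interval,
                           meta={"regime": regime, "step_std": step_std,
                                 "drift_std": drift_std, "seed": seed})
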