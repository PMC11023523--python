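"""Delimited-table readers/writers and run configuration.

All tables are CSV with explicit units in the headers (μm, μm/h, hours).
Field series are stored as one long table (frame, t_h, x_um, y_um,
u_umph, v_umph); masked grid nodes are simply absent and are
reconstructed as invalid on read. Trajectory and defect tables carry a
JSON sidecar for metadata (frame interval, parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import LatticeSpec, SpringNetwork
from .simulate import SimParams
from .synth import TrajectoryTable, VelocityFieldFrame
from .topology import DefectRecord, DefectSet, DetectionParams


class TableFormatError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


# ---------------------------------------------------------------- networks

def write_network(net: SpringNetwork, points_path, springs_path) -> None:
    pd.DataFrame({"id": np.arange(net.n_points),
                  "x_um": net.points[:, 0],
                  "y_um": net.points[:, 1]}).to_csv(points_path, index=False)
    pd.DataFrame({"i": net.edges[:, 0], "j": net.edges[:, 1],
                  "rest_length_um": net.rest_lengths}
                 ).to_csv(springs_path, index=False)
    meta = dict(net.meta)
    if net.spec is not None:
        meta["spec"] = asdict(net.spec)
    _sidecar(points_path).write_text(json.dumps(meta, indent=1))


def read_network(points_path, springs_path) -> SpringNetwork:
    pts = pd.read_csv(points_path, float_precision="round_trip")
    spr = pd.read_csv(springs_path, float_precision="round_trip")
    _require_columns(pts, {"id", "x_um", "y_um"}, points_path)
    _require_columns(spr, {"i", "j", "rest_length_um"}, springs_path)
    spec = None
    meta = {}
    sc = _sidecar(points_path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if "spec" in meta:
            raw = dict(meta.pop("spec"))
            raw["polydispersity_interval"] = tuple(
                raw["polydispersity_interval"])
            spec = LatticeSpec(**raw)
    return SpringNetwork(points=pts[["x_um", "y_um"]].to_numpy(),
                         edges=spr[["i", "j"]].to_numpy(),
                         rest_lengths=spr["rest_length_um"].to_numpy(),
                         spec=spec, meta=meta)


# ------------------------------------------------------------ field series

def write_field_series(frames: list[VelocityFieldFrame], path) -> None:
    rows = []
    for k, f in enumerate(frames):
        X, Y = np.meshgrid(f.x, f.y)
        sel = f.valid()
        rows.append(pd.DataFrame({
            "frame": k, "t_h": f.time,
            "x_um": X[sel], "y_um": Y[sel],
            "u_umph": f.u[sel], "v_umph": f.v[sel]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_field_series(path) -> list[VelocityFieldFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"frame", "t_h", "x_um", "y_um", "u_umph",
                          "v_umph"}, path)
    bad = df.index[~np.isfinite(df[["u_umph", "v_umph"]]).all(axis=1)]
    if len(bad):
        raise TableFormatError(
            f"{path}: non-finite velocity at data rows {list(bad[:5])}")
    frames = []
    for k in sorted(df["frame"].unique()):
        sub = df[df["frame"] == k]
        x = np.unique(sub["x_um"])
        y = np.unique(sub["y_um"])
        u = np.full((len(y), len(x)), np.nan)
        v = np.full_like(u, np.nan)
        mask = np.zeros(u.shape, dtype=bool)
        ix = np.searchsorted(x, sub["x_um"].to_numpy())
        iy = np.searchsorted(y, sub["y_um"].to_numpy())
        u[iy, ix] = sub["u_umph"].to_numpy()
        v[iy, ix] = sub["v_umph"].to_numpy()
        mask[iy, ix] = True
        frames.append(VelocityFieldFrame(
            x=x, y=y, u=np.where(mask, u, 0.0), v=np.where(mask, v, 0.0),
            time=float(sub["t_h"].iloc[0]),
            mask=None if mask.all() else mask))
    return frames


# ------------------------------------------------------------ trajectories

def write_trajectories(table: TrajectoryTable, path) -> None:
    table.data[["track_id", "frame", "x_um", "y_um"]].to_csv(path, index=False)
    meta = {"frame_interval_h": table.frame_interval_h, **table.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trajectories(path, frame_interval_h: float | None = None
                      ) -> TrajectoryTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, {"track_id", "frame", "x_um", "y_um"}, path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if frame_interval_h is None:
        if "frame_interval_h" not in meta:
            raise TableFormatError(
                f"{path}: frame_interval_h not given and no sidecar found")
        frame_interval_h = meta.pop("frame_interval_h")
    else:
        meta.pop("frame_interval_h", None)
    return TrajectoryTable(data=df, frame_interval_h=frame_interval_h,
                           meta=meta)


# ----------------------------------------------------------------- defects

def write_defects(sets: list[DefectSet], path) -> None:
    rows = []
    for s in sets:
        for r in s.records:
            rows.append({"frame": s.frame, "t_h": s.time,
                         "x_um": r.position[0], "y_um": r.position[1],
                         "charge": r.charge, "cluster_size": r.cluster_size})
    cols = ["frame", "t_h", "x_um", "y_um", "charge", "cluster_size"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_defects(sets_path) -> list[DefectSet]:
    df = pd.read_csv(sets_path, float_precision="round_trip")
    _require_columns(df, {"frame", "t_h", "x_um", "y_um", "charge",
                          "cluster_size"}, sets_path)
    zero = df.index[df["charge"] == 0]
    if len(zero):
        raise TableFormatError(
            f"{sets_path}: charge 0 at data rows {list(zero[:5])}")
    out = []
    for k in sorted(df["frame"].unique()):
        sub = df[df["frame"] == k]
        recs = [DefectRecord(frame=int(k),
                             position=np.array([row.x_um, row.y_um]),
                             charge=int(row.charge),
                             cluster_size=int(row.cluster_size))
                for row in sub.itertuples()]
        out.append(DefectSet(frame=int(k), time=float(sub["t_h"].iloc[0]),
                             records=recs))
    return out


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    lattice: LatticeSpec
    sim: SimParams
    detection: DetectionParams
    duration_h: float = 12.0
    snapshot_interval_h: float = 0.25
    grid_spacing_um: float = 66.0
    window_um: float = 165.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        doc = {"lattice": asdict(self.lattice),
               "sim": asdict(self.sim),
               "detection": asdict(self.detection),
               "duration_h": self.duration_h,
               "snapshot_interval_h": self.snapshot_interval_h,
               "grid_spacing_um": self.grid_spacing_um,
               "window_um": self.window_um,
               "seed": self.seed}
        doc["lattice"]["polydispersity_interval"] = list(
            doc["lattice"]["polydispersity_interval"])
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        lat = dict(doc["lattice"])
        lat["polydispersity_interval"] = tuple(lat["polydispersity_interval"])
        return cls(lattice=LatticeSpec(**lat),
                   sim=SimParams(**doc["sim"]),
                   detection=DetectionParams(**doc["detection"]),
                   duration_h=doc["duration_h"],
                   snapshot_interval_h=doc["snapshot_interval_h"],
                   grid_spacing_um=doc["grid_spacing_um"],
                   window_um=doc["window_um"],
                   seed=doc["seed"])
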