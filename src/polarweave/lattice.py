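"""Disordered bead-spring networks for active-elastic-solid simulations.

An epithelial monolayer is represented as a set of point particles ("cells")
in a circular domain, connected by springs along the edges of the Delaunay
triangulation (the adjacency graph of the Voronoi tessellation). The point
set is produced by packing polydisperse repulsive disks so that it is
statistically isotropic: no long-range hexagonal order, which would make the
elasticity of the sheet anisotropic.

Spring rest lengths d_ij are drawn i.i.d. uniform on ``[0.8 d, 1.2 d]``
(mean spacing ``d``), which enforces microscopic lattice disorder while
keeping the mean rest length at ``d``. Alternatively the measured
inter-point distance (clamped to the same interval) can be used, giving a
stress-free initial state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree


class LatticeError(ValueError):
    """Raised for infeasible or degenerate lattice construction requests."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the disordered monolayer lattice.

    Parameters
    ----------
    domain_radius : float
        Radius R of the circular confinement, in μm.
    target_cell_count : int
        Number of cells N to place.
    mean_spacing : float
        Target mean distance d between neighbouring cells, in μm.
    polydispersity_interval : tuple
        Rest lengths (and disk diameters) span this interval as a fraction
        of ``mean_spacing``.
    rng_seed : int
        Seed for the single generator used throughout the build.
    """

    domain_radius: float
    target_cell_count: int
    mean_spacing: float
    polydispersity_interval: tuple[float, float] = (0.8, 1.2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.polydispersity_interval
        if self.domain_radius <= 0:
            raise LatticeError("domain_radius must be positive")
        if self.target_cell_count < 1:
            raise LatticeError("target_cell_count must be >= 1")
        if self.mean_spacing <= 0:
            raise LatticeError("mean_spacing must be positive")
        if not (0 < lo < hi):
            raise LatticeError("polydispersity interval must satisfy 0 < lo < hi")


@dataclass
class SpringNetwork:
    """Bead-spring network: points, edges and per-edge rest lengths (μm)."""

    points: np.ndarray          # (N, 2)
    edges: np.ndarray           # (E, 2) int, i < j
    rest_lengths: np.ndarray    # (E,)
    spec: LatticeSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_points, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def is_connected(self) -> bool:
        if self.n_points == 1:
            return True
        adj = sparse.coo_matrix(
            (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_points, self.n_points),
        )
        n_comp, _ = connected_components(adj, directed=False)
        return n_comp == 1


def _max_hex_spacing(spec: LatticeSpec) -> float:
    """Spacing of a perfect hexagonal packing of N points in the disk."""
    area = math.pi * spec.domain_radius**2
    return math.sqrt(2.0 * area / (math.sqrt(3.0) * spec.target_cell_count))


def scaled_domain_radius(n_cells: int, full_radius: float = 3500.0,
                         full_count: int = 100_000) -> float:
    """Radius of a scaled-down circular domain at the reference cell density.

    The reference monolayer holds 100,000 cells in a 3.5-mm disk; a
    desk-scale run with N cells keeps that density:
    R = 3500 μm · sqrt(N / 100000).
    """
    return full_radius * math.sqrt(n_cells / full_count)


def pack_disks(spec: LatticeSpec, n_growth_steps: int = 12,
               sweeps_per_step: int = 15) -> np.ndarray:
    """Pack N polydisperse repulsive disks in the circular domain.

    Disks are seeded uniformly at random, started at 60% of their target
    radius, then grown stepwise; after each growth step, overlapping pairs
    are pushed apart along their separation (each move strictly lowers the
    pair-overlap energy). Polydisperse target diameters (uniform on the
    rest-length interval) frustrate crystallisation, so the final point set
    carries no long-range hexagonal order.

    Returns an (N, 2) array of positions (μm) inside the domain.
    """
    R, N, d = spec.domain_radius, spec.target_cell_count, spec.mean_spacing
    # Feasibility: the densest (hexagonal) packing of N points in the disk
    # has spacing s_max; if s_max is far below d the request cannot give a
    # mean spacing anywhere near d.
    if N >= 3 and _max_hex_spacing(spec) < 0.75 * d:
        raise LatticeError(
            f"infeasible density: {N} cells at spacing {d} μm exceed the "
            f"capacity of a disk of radius {R} μm"
        )

    # stream namespaced so other seeded stages (network, polarity) with the
    # same base seed stay statistically independent
    rng = np.random.default_rng((spec.rng_seed, 0))
    if N == 1:
        return np.zeros((1, 2))

    # uniform points in the disk
    r = R * np.sqrt(rng.random(N))
    phi = rng.uniform(0, 2 * np.pi, N)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])

    lo, hi = spec.polydispersity_interval
    target_radii = 0.5 * d * rng.uniform(lo, hi, N)
    # Cannot exceed the available area: rescale targets if the request is
    # denser than a hexagonal packing allows (points then sit closer than d).
    s_max = _max_hex_spacing(spec)
    if s_max < d:
        target_radii *= s_max / d

    scales = np.linspace(0.6, 1.0, n_growth_steps)
    for scale in scales:
        radii = scale * target_radii
        rmax = radii.max()
        for _ in range(sweeps_per_step):
            tree = cKDTree(pos)
            pairs = tree.query_pairs(2 * rmax, output_type="ndarray")
            if len(pairs):
                i, j = pairs[:, 0], pairs[:, 1]
                dvec = pos[j] - pos[i]
                dist = np.hypot(dvec[:, 0], dvec[:, 1])
                overlap = radii[i] + radii[j] - dist
                hit = overlap > 0
                if not hit.any():
                    break
                i, j, dvec, dist, overlap = (
                    i[hit], j[hit], dvec[hit], dist[hit], overlap[hit])
                dist = np.maximum(dist, 1e-9 * d)
                push = 0.5 * (overlap / dist)[:, None] * dvec
                np.add.at(pos, j, push)
                np.add.at(pos, i, -push)
            # confine: pull protruding disks back to the rim
            rad = np.hypot(pos[:, 0], pos[:, 1])
            out = rad > R
            if out.any():
                pos[out] *= (R / rad[out])[:, None]
    return pos


def build_network(points: np.ndarray, spec: LatticeSpec,
                  rest_length_mode: str = "uniform",
                  prune_factor: float = 1.5) -> SpringNetwork:
    """Connect packed points into a spring network by Delaunay triangulation.

    Delaunay edges are exactly the adjacencies of the Voronoi tessellation.
    Edges longer than ``prune_factor * d`` (sliver edges along the convex
    hull) are dropped. Rest lengths: ``"uniform"`` draws i.i.d. uniform on
    the polydispersity interval; ``"distance"`` uses the measured
    inter-point distance clamped to the same interval (stress-free start).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise LatticeError("need at least 3 points to triangulate")
    d = spec.mean_spacing
    rng = np.random.default_rng((spec.rng_seed, 1))
    # tiny jitter resolves cocircular Voronoi ties deterministically
    jittered = points + rng.normal(scale=1e-6 * d, size=points.shape)
    try:
        tri = Delaunay(jittered)
    except QhullError as exc:  # pragma: no cover - degenerate input
        raise LatticeError(f"degenerate point set (collinear/duplicate): {exc}")

    # unique undirected edges from the triangle list
    simp = tri.simplices
    e = np.concatenate([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
    e.sort(axis=1)
    edges = np.unique(e, axis=0)

    lengths = np.hypot(*(points[edges[:, 1]] - points[edges[:, 0]]).T)
    keep = lengths <= prune_factor * d
    pruned = edges[~keep]
    pruned_len = lengths[~keep]
    edges, lengths = edges[keep], lengths[keep]
    if len(edges) == 0:
        raise LatticeError("all edges pruned; check spacing vs. density")
    # pruning must not disconnect the network: restore the shortest pruned
    # edges that bridge separate components (the full Delaunay graph is
    # connected, so this always succeeds)
    parent = np.arange(len(points))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    n_comp = len({find(k) for k in range(len(points))})
    if n_comp > 1:
        order = np.argsort(pruned_len)
        restored = []
        for k in order:
            i, j = pruned[k]
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                restored.append(k)
                n_comp -= 1
                if n_comp == 1:
                    break
        if restored:
            edges = np.concatenate([edges, pruned[restored]])
            lengths = np.concatenate([lengths, pruned_len[restored]])

    lo, hi = spec.polydispersity_interval
    if rest_length_mode == "uniform":
        rest = rng.uniform(lo * d, hi * d, size=len(edges))
    elif rest_length_mode == "distance":
        rest = np.clip(lengths, lo * d, hi * d)
    else:
        raise LatticeError(f"unknown rest_length_mode {rest_length_mode!r}")

    net = SpringNetwork(
        points=points, edges=edges, rest_lengths=rest, spec=spec,
        meta={"rng_seed": spec.rng_seed, "rest_length_mode": rest_length_mode,
              "prune_factor": prune_factor},
    )
    if not net.is_connected():
        raise LatticeError("network disconnected after boundary pruning")
    return net


def build_lattice(spec: LatticeSpec, **kwargs) -> SpringNetwork:
    """Pack disks and build the spring network in one call."""
    return build_network(pack_disks(spec), spec, **kwargs)


def hexatic_order(points: np.ndarray) -> float:
    """Mean bond-orientational order |ψ6| over Delaunay neighbours.

    1 for a perfect hexagonal lattice; well below 1 for disordered packings.
    """
    points = np.asarray(points, dtype=float)
    tri = Delaunay(points)
    indptr, indices = tri.vertex_neighbor_vertices
    psi = np.zeros(len(points))
    for i in range(len(points)):
        nbr = indices[indptr[i]:indptr[i + 1]]
        if len(nbr) == 0:
            continue
        vec = points[nbr] - points[i]
        ang = np.arctan2(vec[:, 1], vec[:, 0])
        psi[i] = abs(np.exp(6j * ang).mean())
    return float(psi.mean())
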