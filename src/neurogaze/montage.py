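"""Synthetic scalp montages: electrode positions, region tags, neighbour graph.

A montage is the spatial scaffold for scalp-level statistics: channel labels,
unit-sphere 3-D positions, a coarse region tag per channel (occipital,
frontal, face, other) and a symmetric neighbour graph used for bad-channel
detection and cluster-based permutation tests.  Face channels are excluded
from scalp statistics.

Coordinate convention: x = right, y = anterior, z = superior; the head is the
unit sphere.  Real high-density net geometries are not reproduced — only the
region semantics matter for the analyses in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


@dataclass(frozen=True)
class Montage:
    """Electrode layout on the unit sphere.

    Attributes
    ----------
    labels : tuple of str
        Unique channel labels.
    positions : ndarray, shape (n, 3)
        Unit-norm electrode positions (x right, y anterior, z up).
    regions : tuple of str
        Per-channel tag in {"occipital", "frontal", "face", "other"}.
    adjacency : ndarray, shape (n, n), bool
        Symmetric neighbour matrix, no self-edges.
    """

    labels: tuple
    positions: np.ndarray
    regions: tuple
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self):
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("channel labels must be unique")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("electrode positions must lie on the unit sphere")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be (n, n)")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have no self-edges")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def channel_indices(self, region: str) -> np.ndarray:
        """Indices of channels tagged with ``region``."""
        return np.array([i for i, r in enumerate(self.regions) if r == region],
                        dtype=int)

    @property
    def scalp_mask(self) -> np.ndarray:
        """Boolean mask of non-face channels (the ones entering scalp stats)."""
        return np.array([r != "face" for r in self.regions])

    def neighbor_lists(self) -> list:
        """Adjacency as a list of index arrays, one per channel."""
        return [np.flatnonzero(row) for row in self.adjacency]


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """n roughly equidistant points on the spherical cap z in [z_min, 1]."""
    i = np.arange(n)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _assign_regions(pos: np.ndarray) -> tuple:
    """Region tags from electrode geometry.

    Face: below the equator on the anterior side.  Frontal: anterior upper
    scalp.  Occipital: the lowest 20% of electrodes (by z) on the posterior
    half — the compact patch over visual cortex.  Everything else: other.
    """
    x, y, z = pos.T
    face = (z < 0.0) & (y > 0.35)
    back = (y < 0.0) & ~face
    z_cut = np.quantile(pos[back, 2], 0.20) if back.any() else -np.inf
    occipital = back & (z <= z_cut)
    frontal = (y > 0.45) & (z > -0.05) & ~face
    regions = np.full(len(pos), "other", dtype=object)
    regions[face] = "face"
    regions[occipital] = "occipital"
    regions[frontal & ~occipital] = "frontal"
    return tuple(str(r) for r in regions)


def delaunay_adjacency(positions: np.ndarray, max_angle_deg: float = 30.0) -> np.ndarray:
    """Spherical-Delaunay neighbour graph pruned at a maximum angular distance.

    The convex hull of points on a sphere is the spherical Delaunay
    triangulation; its edges, pruned at ``max_angle_deg`` great-circle
    distance, define the neighbour structure.
    """
    n = positions.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    if n < 4:
        # too few points for a hull: fully connect within the angular limit
        hull_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        hull = ConvexHull(positions)
        hull_edges = set()
        for simplex in hull.simplices:
            for a in range(3):
                i, j = simplex[a], simplex[(a + 1) % 3]
                hull_edges.add((min(i, j), max(i, j)))
    cos_max = np.cos(np.deg2rad(max_angle_deg))
    for i, j in hull_edges:
        if positions[i] @ positions[j] >= cos_max:
            adj[i, j] = adj[j, i] = True
    return adj


def make_montage(n_channels: int = 64, max_angle_deg: float = 30.0,
                 z_min: float = -0.35) -> Montage:
    """Build a synthetic montage of ``n_channels`` electrodes.

    Electrodes are placed as a Fibonacci lattice on the spherical cap
    ``z >= z_min`` (covering scalp plus the lower face/neck rim that
    high-density nets reach).  Regions are assigned from the y/z
    coordinates; neighbours are Delaunay edges pruned at ``max_angle_deg``.

    Parameters
    ----------
    n_channels : int
        Number of electrodes (64 default; 256 supported).
    """
    if n_channels < 4:
        raise ValueError("a montage needs at least 4 channels")
    pos = _fibonacci_cap(n_channels, z_min)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    regions = _assign_regions(pos)
    labels = tuple(f"E{i + 1}" for i in range(n_channels))
    # prune angle scales with density so 256-channel nets stay locally connected
    angle = max_angle_deg if n_channels <= 96 else max_angle_deg * np.sqrt(64 / n_channels)
    adj = delaunay_adjacency(pos, angle)
    return Montage(labels=labels, positions=pos, regions=regions, adjacency=adj)
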