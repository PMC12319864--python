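"""Cortical surface meshes: geometry, adjacency, areas, and icosphere synthesis.

A :class:`SurfaceMesh` carries two coordinate systems for the same triangulation:
the folded white-matter surface (mm, used for distances, endpoint assignment and
areas) and the spherical registration (unit vectors, used by the spin test).
A boolean medial-wall mask flags non-cortical vertices excluded from analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh

#: White-surface radius used for synthetic spheres, mm (brain-like scale).
WHITE_RADIUS_MM = 60.0

#: Angular radius of the synthetic medial-wall cap, degrees.
MEDIAL_CAP_DEG = 20.0


@dataclass
class SurfaceMesh:
    white_coords: np.ndarray      # (V, 3) mm
    sphere_coords: np.ndarray     # (V, 3) unit norm
    triangles: np.ndarray         # (F, 3) int
    medial_mask: np.ndarray       # (V,) bool, True = medial wall (excluded)

    def __post_init__(self) -> None:
        self.white_coords = np.asarray(self.white_coords, dtype=float)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.medial_mask = np.asarray(self.medial_mask, dtype=bool)
        v = self.white_coords.shape[0]
        if self.sphere_coords.shape != (v, 3) or self.medial_mask.shape != (v,):
            raise ValueError("inconsistent vertex counts across mesh arrays")

    @property
    def n_vertices(self) -> int:
        return self.white_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def cortex_mask(self) -> np.ndarray:
        """Boolean mask of analysed (non-medial-wall) vertices."""
        return ~self.medial_mask

    @property
    def cortex_indices(self) -> np.ndarray:
        return np.flatnonzero(self.cortex_mask)

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.arange(self.n_vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), each row sorted."""
        tri = self.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric vertex adjacency with Euclidean white-surface edge lengths."""
        e = self.edges()
        d = np.linalg.norm(self.white_coords[e[:, 0]] - self.white_coords[e[:, 1]], axis=1)
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.concatenate([d, d])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_vertices,) * 2)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident triangle's area (mm^2)."""
        p = self.white_coords[self.triangles]
        tri_area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        areas = np.zeros(self.n_vertices)
        for j in range(3):
            np.add.at(areas, self.triangles[:, j], tri_area / 3.0)
        return areas

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles


def make_sphere_mesh(subdivision_level: int) -> SurfaceMesh:
    """Icosphere stand-in for a registered cortical hemisphere surface.

    The white surface is the sphere scaled to 60 mm radius; the spherical
    registration is the unit sphere itself. A geodesic cap of 20 degrees around
    the -z pole (always containing at least the pole-nearest vertex) is flagged
    as medial wall.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    sphere = np.asarray(ico.vertices, dtype=float)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    tris = np.asarray(ico.faces, dtype=int)
    cos_cap = np.cos(np.deg2rad(MEDIAL_CAP_DEG))
    medial = sphere[:, 2] <= -cos_cap
    if not medial.any():
        medial[int(np.argmin(sphere[:, 2]))] = True
    return SurfaceMesh(
        white_coords=WHITE_RADIUS_MM * sphere,
        sphere_coords=sphere,
        triangles=tris,
        medial_mask=medial,
    )
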