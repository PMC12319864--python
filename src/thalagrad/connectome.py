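"""From streamline endpoints to a smoothed, filtered, normalized connectome.

Stages, in pipeline order:

1. ``assign_endpoints`` — each streamline endpoint is assigned to the nearest
   non-medial-wall vertex within a fixed radius (default 5 mm) and contributes
   its mean-FA weight to the (seed, vertex) cell.
2. ``build_kernel`` / ``smooth_connectome`` — connectome spatial smoothing
   with a geodesic Gaussian kernel (default 3 mm FWHM, 0.01 truncation) over
   the cortical vertex dimension, to mitigate endpoint placement error.
3. ``filter_seeds`` — seeds whose across-subject mean row touches fewer than a
   minimum number of vertices (default 100) are dropped: deep/medial seeds
   with unreliably low cortical connectivity.
4. ``normalize_sigmoid`` — per cortical connection (matrix column), the scaled
   sigmoid S(x) = 1 / (1 + exp(-(x - <x>)/sigma_x)) with the column mean and
   population sd across seeds, followed by a per-column min-max rescale to
   [0, 1]; an outlier-robust normalization.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from scipy.special import expit

from .core import ConnectivityMatrix
from .surfaces import SurfaceMesh

__all__ = [
    "SmoothingKernel",
    "NormalizationParams",
    "assign_endpoints",
    "build_kernel",
    "build_seed_kernel",
    "smooth_connectome",
    "filter_seeds",
    "normalize_sigmoid",
]

logger = logging.getLogger(__name__)


@dataclass
class SmoothingKernel:
    """Row-stochastic vertex-to-vertex Gaussian smoothing weights.

    Row u holds the weights with which vertex u's connectivity mass is
    redistributed to nearby vertices; applying the kernel on the right
    (``values @ matrix``) therefore conserves each seed's total connectivity.
    Medial-wall rows and columns are identity, so no mass enters or leaves
    the medial wall.
    """

    matrix: sp.csr_matrix
    fwhm: float
    epsilon: float

    def __post_init__(self) -> None:
        sums = np.asarray(self.matrix.sum(axis=1)).ravel()
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("kernel rows must sum to 1 within 1e-8")
        if np.any(self.matrix.diagonal() <= 0):
            raise ValueError("kernel diagonal must be strictly positive")


@dataclass
class NormalizationParams:
    """Per-vertex statistics of the scaled-sigmoid normalization."""

    column_mean: np.ndarray   # <x> across seeds
    column_sd: np.ndarray     # population sigma_x across seeds
    post_min: np.ndarray      # sigmoid minimum used for linear scaling
    post_max: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.column_sd < 0):
            raise ValueError("column sd must be non-negative")
        if np.any(self.post_min > self.post_max):
            raise ValueError("post-sigmoid min must not exceed max")


def assign_endpoints(
    endpoints: pd.DataFrame,
    mesh: SurfaceMesh,
    seed_ids: np.ndarray,
    radius: float = 5.0,
) -> ConnectivityMatrix:
    """Accumulate per-streamline FA weights onto nearest cortical vertices.

    An endpoint is assigned to the closest non-medial-wall vertex by Euclidean
    distance on the white surface; streamlines landing farther than ``radius``
    from every cortical vertex are discarded. Medial-wall vertices never
    receive weight.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    seed_ids = np.asarray(seed_ids)
    values = np.zeros((len(seed_ids), mesh.n_vertices))
    if len(endpoints) == 0:
        warnings.warn("empty endpoint table; returning an all-zero connectome")
        return ConnectivityMatrix(values, seed_ids, mesh.vertex_ids, state="raw")
    if (endpoints["fa"] < 0).any():
        raise ValueError("negative FA weights in endpoint table")
    seed_pos = {sid: i for i, sid in enumerate(seed_ids.tolist())}
    unknown = set(endpoints["seed_id"]) - set(seed_pos)
    if unknown:
        raise ValueError(f"endpoint seed ids not in the seed list: {sorted(unknown)[:5]}")

    cortex = mesh.cortex_indices
    tree = cKDTree(mesh.white_coords[cortex])
    xyz = endpoints[["x", "y", "z"]].to_numpy(dtype=float)
    dist, nearest = tree.query(xyz)
    keep = dist <= radius
    rows = np.array([seed_pos[s] for s in endpoints["seed_id"]])[keep]
    cols = cortex[nearest[keep]]
    np.add.at(values, (rows, cols), endpoints["fa"].to_numpy(dtype=float)[keep])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("discarded %d endpoints beyond %.1f mm of the cortex", n_dropped, radius)
    return ConnectivityMatrix(values, seed_ids, mesh.vertex_ids, state="raw")


def build_kernel(mesh: SurfaceMesh, fwhm: float = 3.0, epsilon: float = 0.01) -> SmoothingKernel:
    """Geodesic Gaussian smoothing kernel over the cortical mesh.

    Geodesic distance is approximated by shortest paths on the mesh edge graph
    with Euclidean white-surface edge lengths. Raw weights exp(-d^2/(2 sigma^2))
    with sigma = fwhm / (2 sqrt(2 ln 2)) are truncated below ``epsilon`` and
    rows renormalized to sum 1. Raises if the cortical (non-medial) subgraph
    is disconnected.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    cortex = mesh.cortex_indices
    adj = mesh.adjacency()[cortex][:, cortex]
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"cortical mesh is disconnected ({n_comp} components) after medial-wall removal"
        )
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # beyond d_max the raw Gaussian weight is already < epsilon
    if epsilon > 0:
        d_max = sigma * np.sqrt(2.0 * np.log(1.0 / epsilon))
    else:
        d_max = np.inf
    dists = dijkstra(adj, directed=False, limit=d_max)
    with np.errstate(over="ignore"):
        w = np.exp(-(dists**2) / (2.0 * sigma**2))
    w[~np.isfinite(dists)] = 0.0
    w[w < epsilon] = 0.0
    np.fill_diagonal(w, np.maximum(np.diag(w), 1.0))  # self-weight survives truncation
    w /= w.sum(axis=1, keepdims=True)

    ii, jj = np.nonzero(w)
    medial = np.flatnonzero(mesh.medial_mask)
    rows = np.concatenate([cortex[ii], medial])
    cols = np.concatenate([cortex[jj], medial])
    data = np.concatenate([w[ii, jj], np.ones(len(medial))])
    full = sp.csr_matrix((data, (rows, cols)), shape=(mesh.n_vertices,) * 2)
    return SmoothingKernel(full, fwhm=fwhm, epsilon=epsilon)


def build_seed_kernel(seed_coordinates: np.ndarray, fwhm: float,
                      epsilon: float = 0.01) -> np.ndarray:
    """Optional volumetric Gaussian kernel over the thalamic seed dimension.

    Seeds live in volume, not on a mesh, so distances are Euclidean between
    seed coordinates (mm). Row-stochastic, same truncation rule as the
    cortical kernel. Off by default in the pipeline: the cortical dimension is
    the one smoothing is defined on.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    coords = np.asarray(seed_coordinates, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    w[w < epsilon] = 0.0
    return w / w.sum(axis=1, keepdims=True)


def smooth_connectome(matrix: ConnectivityMatrix, kernel: SmoothingKernel,
                      seed_kernel: np.ndarray | None = None) -> ConnectivityMatrix:
    """Redistribute connectivity over the cortical dimension with the kernel.

    Mass-conserving: the row-stochastic kernel is applied on the right, so each
    seed's total connectivity is unchanged. If a ``seed_kernel`` is supplied
    (see :func:`build_seed_kernel`), connectivity is additionally smoothed over
    the thalamic seed dimension first.
    """
    if matrix.state != "raw":
        raise ValueError(f"smoothing expects a raw matrix, got state={matrix.state!r}")
    if kernel.matrix.shape[0] != matrix.n_vertices:
        raise ValueError(
            f"kernel has {kernel.matrix.shape[0]} vertices, matrix has {matrix.n_vertices}"
        )
    values = matrix.values
    if seed_kernel is not None:
        if seed_kernel.shape != (matrix.n_seeds, matrix.n_seeds):
            raise ValueError("seed kernel dimension does not match the seed count")
        values = seed_kernel @ values
    smoothed = np.asarray(values @ kernel.matrix)
    return matrix.with_values(np.maximum(smoothed, 0.0), state="smoothed")


def filter_seeds(group_mean_matrix: ConnectivityMatrix, min_connected_vertices: int = 100) -> np.ndarray:
    """Indices of seeds connected to at least ``min_connected_vertices`` vertices.

    Operates on the across-subject mean matrix; a seed counts as connected to a
    vertex iff the mean weight there is strictly positive. Raises if no seed
    survives.
    """
    nonzero_counts = (group_mean_matrix.values > 0).sum(axis=1)
    retained = np.flatnonzero(nonzero_counts >= min_connected_vertices)
    if len(retained) == 0:
        raise ValueError(
            f"all {group_mean_matrix.n_seeds} seeds fall below "
            f"{min_connected_vertices} connected vertices"
        )
    logger.info(
        "seed filter removed %d of %d seeds (<%d connected vertices)",
        group_mean_matrix.n_seeds - len(retained), group_mean_matrix.n_seeds,
        min_connected_vertices,
    )
    return np.sort(retained)


def normalize_sigmoid(matrix: ConnectivityMatrix) -> tuple[ConnectivityMatrix, NormalizationParams]:
    """Scaled-sigmoid normalization of each cortical connection to [0, 1].

    Per column: S(x) = 1 / (1 + exp(-(x - <x>)/sigma_x)) with the column mean
    and population standard deviation across seeds, then a linear rescale
    mapping the column minimum to 0 and maximum to 1. Zero-variance columns
    (sigma_x = 0, where the sigmoid is undefined) are set to the constant 0.5,
    its symmetric limit.
    """
    if matrix.state not in ("smoothed", "filtered"):
        raise ValueError(f"normalization expects a smoothed/filtered matrix, got {matrix.state!r}")
    if matrix.n_seeds < 2:
        raise ValueError("need at least 2 seeds to normalize across seeds")
    x = matrix.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (divide-by-n) sd
    varying = sd > 0
    z = np.zeros_like(x)
    z[:, varying] = (x[:, varying] - mean[varying]) / sd[varying]
    s = expit(z)
    post_min = s.min(axis=0)
    post_max = s.max(axis=0)
    out = np.full_like(s, 0.5)
    span = post_max - post_min
    scalable = varying & (span > 0)
    out[:, scalable] = (s[:, scalable] - post_min[scalable]) / span[scalable]
    params = NormalizationParams(mean, sd, post_min, post_max)
    return matrix.with_values(out, state="normalized"), params
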