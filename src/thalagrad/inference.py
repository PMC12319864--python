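"""Spatial statistics on thalamic seed maps and cortical surface maps.

Implements the study's inferential machinery:

- spin tests: spatial-autocorrelation-preserving permutation nulls built by
  randomly rotating the spherical registration and remapping vertex values,
  with bidirectional averaging of the two directional p-values;
- vertexwise / seedwise age-correlation maps with Benjamini-Hochberg FDR;
- Cartesian-axis correlations of seed maps;
- a vertexwise two-group GLM (group + scan age + sex) with Freedman-Lane
  permutation of reduced-model residuals, optional threshold-free cluster
  enhancement (TFCE), and max-statistic family-wise error control;
- an ANCOVA-style F test for scalar outcomes (e.g. variance-explained
  fractions) controlling for covariates.

Permutation p-values use the add-one convention (1 + #exceedances)/(1 + n)
throughout, so they are never exactly zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .core import ConnectivityMatrix, SeedGrid
from .surfaces import SurfaceMesh

__all__ = [
    "SpinPermutationSet",
    "StatMap",
    "DesignMatrix",
    "make_spins",
    "spin_test",
    "fdr_bh",
    "age_correlation_map",
    "axis_correlation",
    "vertex_totals",
    "glm_tmap",
    "tfce_enhance",
    "permutation_fwer",
    "group_scalar_ancova",
]

ALPHA = 0.05


@dataclass
class SpinPermutationSet:
    """Vertex remappings from random sphere rotations.

    ``indices[p, i]`` is the position (within the non-medial-wall vertex list)
    of the original vertex whose value vertex i receives under permutation p.
    """

    indices: np.ndarray          # (n_perm, n_cortex) int
    cortex_indices: np.ndarray   # (n_cortex,) mesh vertex indices
    rng_seed: int

    @property
    def n_perm(self) -> int:
        return self.indices.shape[0]


@dataclass
class StatMap:
    """Per-seed or per-vertex statistic with its p-values and significance mask."""

    values: np.ndarray
    p: np.ndarray
    domain: str                  # {"thalamus", "cortex"}
    p_adjusted: np.ndarray | None = None
    mask: np.ndarray | None = None
    element_ids: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        ids = self.element_ids if self.element_ids is not None else np.arange(len(self.values))
        return pd.DataFrame(
            {
                "id": ids,
                "statistic": self.values,
                "p": self.p,
                "p_adjusted": self.p_adjusted if self.p_adjusted is not None else np.nan,
                "mask": self.mask if self.mask is not None else False,
            }
        )


@dataclass
class DesignMatrix:
    """Per-subject design with a single contrast vector."""

    matrix: np.ndarray           # (n_subjects, p)
    contrast: np.ndarray         # (p,)
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (self.matrix.shape[1],):
            raise ValueError("contrast length must equal design column count")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]


def group_design(group: np.ndarray, scan_age: np.ndarray, sex: np.ndarray,
                 test_group: str = "preterm") -> DesignMatrix:
    """Intercept + group indicator + scan age + sex, contrast on the group."""
    g = (np.asarray(group) == test_group).astype(float)
    s = (np.asarray(sex) == "M").astype(float)
    x = np.column_stack([np.ones(len(g)), g, np.asarray(scan_age, float), s])
    return DesignMatrix(x, np.array([0.0, 1.0, 0.0, 0.0]),
                        ["intercept", "group", "scan_age", "sex"])


# ---------------------------------------------------------------------------
# spin tests


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation: QR of a Gaussian triple, determinant forced to +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _spin_indices(sphere_cortex: np.ndarray, tree: cKDTree, rotation: np.ndarray) -> np.ndarray:
    rotated = sphere_cortex @ rotation.T
    return tree.query(rotated)[1]


def make_spins(mesh: SurfaceMesh, n_perm: int, rng_seed: int) -> SpinPermutationSet:
    """Random-rotation vertex remappings on the spherical registration.

    Each permutation rotates the non-medial-wall sphere coordinates by a
    Haar-uniform rotation and matches every rotated vertex to its nearest
    original vertex (Euclidean, equivalent to angular, distance).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng_seed)
    cortex = mesh.cortex_indices
    sphere = mesh.sphere_coords[cortex]
    tree = cKDTree(sphere)
    idx = np.empty((n_perm, len(cortex)), dtype=int)
    for p in range(n_perm):
        idx[p] = _spin_indices(sphere, tree, _random_rotation(rng))
    return SpinPermutationSet(idx, cortex, rng_seed)


def _cortex_values(a: np.ndarray, spins: SpinPermutationSet) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape[0] == len(spins.cortex_indices):
        return a
    return a[spins.cortex_indices]


def _null_abs_correlations(spun_source: np.ndarray, fixed: np.ndarray,
                           spins: SpinPermutationSet) -> np.ndarray:
    za = spun_source[spins.indices]  # (n_perm, n_cortex)
    za = za - za.mean(axis=1, keepdims=True)
    sa = za.std(axis=1)
    zb = fixed - fixed.mean()
    sb = zb.std()
    r = (za @ zb) / (za.shape[1] * sa * sb)
    return np.abs(r)


def spin_test(map_a: np.ndarray, map_b: np.ndarray,
              spins: SpinPermutationSet) -> tuple[float, float]:
    """Bidirectional spin test of the correlation between two cortical maps.

    Returns (r_observed, p_spin). Each direction spins one map and correlates
    it with the other; directional two-sided p-values use the add-one rule and
    the reported p_spin is their average. Maps may be full-length (all mesh
    vertices) or already restricted to non-medial-wall vertices.
    """
    a = _cortex_values(map_a, spins)
    b = _cortex_values(map_b, spins)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("spin test undefined for a constant map")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    p_vals = []
    for source, fixed in ((a, b), (b, a)):
        null_abs = _null_abs_correlations(source, fixed, spins)
        p_vals.append((1.0 + np.sum(null_abs >= abs(r_obs))) / (1.0 + spins.n_perm))
    return r_obs, float(np.mean(p_vals))


# ---------------------------------------------------------------------------
# mass-univariate correlation maps


def fdr_bh(p_values: np.ndarray, q: float = ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask at q)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return p_adj, reject


def _pearson_vs_covariate(values: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided t-distribution p per column."""
    n = values.shape[0]
    zc = covariate - covariate.mean()
    sc = zc.std()
    zv = values - values.mean(axis=0)
    sv = zv.std(axis=0)
    constant = sv == 0
    sv_safe = np.where(constant, 1.0, sv)
    r = (zc @ zv) / (n * sc * sv_safe)
    r[constant] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[constant] = np.nan
    return r, p


def age_correlation_map(
    values: np.ndarray,
    ages: np.ndarray,
    domain: str,
    q: float = ALPHA,
    element_ids: np.ndarray | None = None,
) -> StatMap:
    """Per-element Pearson correlation with scan age, FDR-masked.

    ``values`` is subjects x elements (aligned scores per seed, or aligned
    loadings per vertex, stacked across subjects). Constant elements get NaN
    and are excluded from the FDR family.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects for an age correlation map")
    if values.shape[0] != len(ages):
        raise ValueError("one age per subject row required")
    r, p = _pearson_vs_covariate(values, ages)
    ok = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    mask = np.zeros(len(p), dtype=bool)
    if ok.any():
        p_adj[ok], mask[ok] = fdr_bh(p[ok], q=q)
    return StatMap(values=r, p=p, domain=domain, p_adjusted=p_adj, mask=mask,
                   element_ids=element_ids)


def axis_correlation(seed_values: np.ndarray, seed_grid: SeedGrid, axis: str) -> tuple[float, float]:
    """Pearson correlation of a per-seed map with one Cartesian seed coordinate."""
    axes = {"x": 0, "y": 1, "z": 2}
    if axis not in axes:
        raise ValueError("axis must be one of 'x', 'y', 'z'")
    seed_values = np.asarray(seed_values, dtype=float)
    if len(seed_values) != seed_grid.n_seeds:
        raise ValueError("one value per seed required")
    r, p = stats.pearsonr(seed_values, seed_grid.coordinates[:, axes[axis]])
    return float(r), float(p)


def vertex_totals(matrix: ConnectivityMatrix, proportion: bool = False) -> np.ndarray:
    """Total connectivity of each vertex to the thalamus (column sums over seeds).

    With ``proportion=True`` the totals are divided by their sum, giving each
    vertex's share of the subject's overall thalamocortical connectivity
    (removes global per-subject scale differences).
    """
    if matrix.state not in ("smoothed", "filtered"):
        raise ValueError(
            f"vertex totals are defined pre-normalization (smoothed/filtered), got {matrix.state!r}"
        )
    totals = matrix.values.sum(axis=0)
    if proportion:
        grand = totals.sum()
        if grand == 0:
            raise ValueError("cannot form connectivity proportions of an all-zero matrix")
        totals = totals / grand
    return totals


# ---------------------------------------------------------------------------
# group GLM, TFCE, permutation FWER


def _tstats(y: np.ndarray, x: np.ndarray, contrast: np.ndarray,
            warn_degenerate: bool = True) -> np.ndarray:
    """OLS t-statistics of a contrast, vectorized over outcome columns."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    c_var = float(contrast @ xtx_inv @ contrast)
    denom = np.sqrt(sigma2 * c_var)
    effect = contrast @ beta
    zero_resid = denom == 0
    if zero_resid.any() and warn_degenerate:
        warnings.warn("zero-residual fit: t statistic is degenerate (infinite)")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / denom
    t[zero_resid & (effect != 0)] = np.sign(effect[zero_resid & (effect != 0)]) * np.inf
    t[zero_resid & (effect == 0)] = 0.0
    return t


def glm_tmap(Y: np.ndarray, design: DesignMatrix, domain: str = "cortex",
             element_ids: np.ndarray | None = None) -> StatMap:
    """Per-vertex OLS t-map for the design's contrast (two-tailed p, n-p df)."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != design.n:
        raise ValueError("one outcome row per design row required")
    if design.n < design.rank + 1:
        raise ValueError("need more subjects than design columns")
    t = _tstats(Y, design.matrix, design.contrast)
    dof = design.n - design.rank
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return StatMap(values=t, p=p, domain=domain, element_ids=element_ids)


def _cluster_increment(values: np.ndarray, adj: sp.csr_matrix, areas: np.ndarray,
                       h: float, E: float, H: float, dh: float) -> np.ndarray:
    """TFCE increment at one threshold: extent^E * h^H * dh per supra vertex."""
    supra = values >= h
    out = np.zeros(len(values))
    if not supra.any():
        return out
    sub = adj[supra][:, supra]
    _, labels = connected_components(sub, directed=False)
    extents = np.bincount(labels, weights=areas[supra])
    out[supra] = extents[labels] ** E * h**H * dh
    return out


def tfce_enhance(
    stat_map: np.ndarray,
    mesh: SurfaceMesh,
    H: float = 2.0,
    E: float = 0.5,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed vertex map.

    For each sign separately, integrates extent(h)^E * h^H over thresholds
    h = dh, 2dh, ... where extent is the surface area (barycentric vertex
    areas) of the supra-threshold connected component containing the vertex,
    with edge connectivity on the cortical (non-medial) mesh. Negative values
    are enhanced on the negated map and re-negated. Default dh = max|t|/100.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat_map)):
        raise ValueError("TFCE requires finite statistics")
    if H <= 0 or E <= 0:
        raise ValueError("H and E must be positive")
    cortex = mesh.cortex_indices
    vals_full = np.zeros(mesh.n_vertices)
    if stat_map.shape[0] == mesh.n_vertices:
        vals_full[:] = stat_map
        vals_full[mesh.medial_mask] = 0.0
    elif stat_map.shape[0] == len(cortex):
        vals_full[cortex] = stat_map
    else:
        raise ValueError("stat map length matches neither all vertices nor the cortex")
    v = vals_full[cortex]
    adj = (mesh.adjacency()[cortex][:, cortex] > 0).astype(np.int8).tocsr()
    areas = mesh.vertex_areas()[cortex]
    vmax = np.abs(v).max()
    if vmax == 0:
        return np.zeros_like(stat_map)
    if dh is None:
        dh = vmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    enhanced = np.zeros(len(v))
    for sign in (1.0, -1.0):
        side = np.maximum(sign * v, 0.0)
        top = side.max()
        if top == 0:
            continue
        h = dh
        while h <= top + 1e-12:
            enhanced += sign * _cluster_increment(side, adj, areas, h, E, H, dh)
            h += dh
    if stat_map.shape[0] == mesh.n_vertices:
        out = np.zeros(mesh.n_vertices)
        out[cortex] = enhanced
        return out
    return enhanced


def permutation_fwer(
    Y: np.ndarray,
    design: DesignMatrix,
    n_perm: int,
    rng_seed: int,
    use_tfce: bool = False,
    mesh: SurfaceMesh | None = None,
    alpha: float = ALPHA,
    tfce_H: float = 2.0,
    tfce_E: float = 0.5,
) -> StatMap:
    """Max-statistic permutation FWER control of a vertexwise group contrast.

    Freedman-Lane scheme: residuals of the reduced (covariates-only) model are
    permuted across subjects, added back to the reduced-model fit, and the full
    model is refitted to each permuted dataset. The per-vertex family-wise
    p-value compares the observed |statistic| (optionally TFCE-enhanced, in
    which case ``mesh`` is required and a common dh from the observed map is
    used for all permutations) against the permutation distribution of the
    map-wise maximum, with the add-one rule.
    """
    Y = np.asarray(Y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 19:
        warnings.warn(f"n_perm={n_perm} cannot reach p < 0.05 (minimum p is 1/(1+n_perm))")
    if use_tfce and mesh is None:
        raise ValueError("TFCE enhancement requires the surface mesh")
    rng = np.random.default_rng(rng_seed)
    x = design.matrix
    keep = design.contrast == 0
    if keep.all() or (~keep).sum() != 1:
        raise ValueError("permutation inference requires a contrast on exactly one column")
    z = x[:, keep]
    hz_y = z @ np.linalg.lstsq(z, Y, rcond=None)[0]
    resid_z = Y - hz_y

    def stat_of(y: np.ndarray, warn: bool) -> np.ndarray:
        t = _tstats(y, x, design.contrast, warn_degenerate=warn)
        if use_tfce:
            return tfce_enhance(t, mesh, H=tfce_H, E=tfce_E, dh=dh_common)
        return t

    if use_tfce:
        t_obs_raw = _tstats(Y, x, design.contrast)
        dh_common = max(np.abs(t_obs_raw).max(), 1e-12) / 100.0
    obs = stat_of(Y, warn=True)
    max_null = np.empty(n_perm)
    exceed = np.zeros(Y.shape[1])
    for pidx in range(n_perm):
        perm = rng.permutation(design.n)
        null_stat = np.abs(stat_of(hz_y + resid_z[perm], warn=False))
        m = null_stat.max()
        max_null[pidx] = m
        exceed += m >= np.abs(obs)
    p_fwer = (1.0 + exceed) / (1.0 + n_perm)
    return StatMap(values=obs, p=p_fwer, domain="cortex", mask=p_fwer < alpha)


def group_scalar_ancova(values: np.ndarray, design: DesignMatrix) -> tuple[float, float]:
    """F-test of the group column for a per-subject scalar, given covariates.

    Compares the covariates-only model against covariates + group: numerator
    df 1, denominator df n - full-model rank.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != design.n:
        raise ValueError("one value per subject required")
    if design.n <= design.rank:
        raise ValueError("need more subjects than design columns")
    x = design.matrix
    keep = design.contrast == 0
    if (~keep).sum() != 1:
        raise ValueError("ancova requires a contrast on exactly one column")
    z = x[:, keep]

    def rss(mat: np.ndarray) -> float:
        beta = np.linalg.lstsq(mat, values, rcond=None)[0]
        return float(((values - mat @ beta) ** 2).sum())

    rss_full = rss(x)
    rss_red = rss(z)
    df2 = design.n - design.rank
    if rss_full <= 1e-12 * max(1.0, rss_red):
        warnings.warn("zero-residual fit: F statistic is degenerate")
        return float("inf"), 0.0
    f = (rss_red - rss_full) / (rss_full / df2)
    p = float(stats.f.sf(f, 1, df2))
    return float(f), p
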