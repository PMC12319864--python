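"""Principal thalamocortical gradients and template alignment.

The normalized seed-by-vertex matrix M is column-centred and decomposed by
thin SVD, M = U S V^T. Scores (US, one row per thalamic seed) and loadings
(V, one row per cortical vertex) jointly describe a gradient: a seed with a
positive score connects preferentially to cortex with positive loadings on
that component. Variance explained per component is lambda_k = s_k^2/(n-1).

Individual decompositions are aligned to a "term template" — the decomposition
of the averaged matrix of the oldest term-born subjects — by an orthogonal
Procrustes rotation fitted on the first ``k_align`` score columns and applied
to both scores and loadings. Reflections are permitted: independent SVDs
differ by arbitrary sign flips which a pure rotation could not undo.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .core import CohortTable, ConnectivityMatrix
from .surfaces import SurfaceMesh

__all__ = [
    "Decomposition",
    "AlignedDecomposition",
    "TemplateBundle",
    "center_matrix",
    "pca_svd",
    "build_template",
    "procrustes_align",
    "similarity_to_template",
]

DEFAULT_K_ALIGN = 5
DEFAULT_N_TEMPLATE = 20


@dataclass
class Decomposition:
    scores: np.ndarray             # (n_seeds, k) = U S
    loadings: np.ndarray           # (n_vertices, k) = V
    singular_values: np.ndarray    # (k,), non-increasing
    variance_explained: np.ndarray  # (k,), lambda_k = s_k^2 / (n - 1)
    variance_fraction: np.ndarray  # (k,), lambda_k / total variance
    column_means: np.ndarray       # per-vertex means removed at centring

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class AlignedDecomposition:
    base: Decomposition
    rotation: np.ndarray           # (k_align, k_align), orthogonal
    aligned_scores: np.ndarray     # scores[:, :k_align] @ rotation
    aligned_loadings: np.ndarray   # loadings[:, :k_align] @ rotation

    @property
    def k_align(self) -> int:
        return self.rotation.shape[0]


@dataclass
class TemplateBundle:
    mean_matrix: ConnectivityMatrix
    decomposition: Decomposition
    subject_ids: np.ndarray


def center_matrix(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Subtract each vertex column's across-seed mean (recorded for reuse)."""
    if matrix.state != "normalized":
        raise ValueError(f"centring expects a normalized matrix, got {matrix.state!r}")
    means = matrix.values.mean(axis=0)
    out = matrix.with_values(matrix.values - means, state="centred")
    out.column_means = means  # type: ignore[attr-defined]
    return out


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Resolve SVD sign ambiguity: largest-|.| loading entry positive, in place."""
    for j in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def pca_svd(matrix: ConnectivityMatrix, k: int) -> Decomposition:
    """Thin SVD of a centred matrix, truncated to k components.

    Total variance (the denominator of the variance fractions) is the full
    column variance of the centred matrix, ||M||_F^2 / (n - 1).
    """
    if matrix.state != "centred":
        raise ValueError(f"decomposition expects a centred matrix, got {matrix.state!r}")
    n, m = matrix.values.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k={k} out of range for a {n}x{m} matrix")
    u, s, vt = np.linalg.svd(matrix.values, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    _fix_signs(scores, loadings)
    lam = s[:k] ** 2 / (n - 1)
    total = (s**2).sum() / (n - 1)
    column_means = getattr(matrix, "column_means", np.zeros(m))
    return Decomposition(
        scores=scores,
        loadings=loadings,
        singular_values=s[:k].copy(),
        variance_explained=lam,
        variance_fraction=lam / total if total > 0 else np.zeros(k),
        column_means=np.asarray(column_means),
    )


def decompose_normalized(matrix: ConnectivityMatrix, k: int) -> Decomposition:
    """Convenience: centre a normalized matrix, then decompose."""
    return pca_svd(center_matrix(matrix), k)


def build_template(
    matrices: list[ConnectivityMatrix],
    phenotypes: CohortTable,
    n_template: int = DEFAULT_N_TEMPLATE,
    k: int = DEFAULT_K_ALIGN,
    exclude_ids: set[str] | None = None,
) -> TemplateBundle:
    """Average the oldest term-born subjects' normalized matrices and decompose.

    ``exclude_ids`` supports leave-one-out templates: those subjects are never
    selected. Raises if fewer than ``n_template`` eligible term subjects exist.
    """
    if len(matrices) != len(phenotypes):
        raise ValueError("one matrix per phenotype row required")
    exclude_ids = exclude_ids or set()
    eligible = np.flatnonzero(
        phenotypes.term_mask() & ~np.isin(phenotypes.subject_ids, list(exclude_ids))
    )
    if len(eligible) < n_template:
        raise ValueError(
            f"only {len(eligible)} eligible term subjects for a template of {n_template}"
        )
    order = eligible[np.argsort(phenotypes.scan_age[eligible])][::-1]
    chosen = np.sort(order[:n_template])
    mean_values = np.mean([matrices[i].values for i in chosen], axis=0)
    mean_matrix = matrices[chosen[0]].with_values(mean_values, state="normalized")
    decomposition = pca_svd(center_matrix(mean_matrix), k)
    return TemplateBundle(mean_matrix, decomposition, phenotypes.subject_ids[chosen])


def procrustes_align(
    individual: Decomposition, template: Decomposition, k_align: int = DEFAULT_K_ALIGN
) -> AlignedDecomposition:
    """Orthogonal Procrustes alignment of an individual to the template.

    Finds the orthogonal R (reflections permitted; no scaling or translation)
    minimizing ||scores_ind[:, :k] R - scores_tmpl[:, :k]||_F, fitted on the
    score (US) matrices, and applies it to both scores and loadings.
    """
    if individual.k < k_align or template.k < k_align:
        raise ValueError(f"both decompositions need >= {k_align} components")
    if individual.scores.shape[0] != template.scores.shape[0]:
        raise ValueError(
            f"seed-count mismatch: {individual.scores.shape[0]} vs {template.scores.shape[0]}"
        )
    rotation, _ = orthogonal_procrustes(
        individual.scores[:, :k_align], template.scores[:, :k_align]
    )
    return AlignedDecomposition(
        base=individual,
        rotation=rotation,
        aligned_scores=individual.scores[:, :k_align] @ rotation,
        aligned_loadings=individual.loadings[:, :k_align] @ rotation,
    )


def similarity_to_template(
    aligned: AlignedDecomposition,
    template: Decomposition,
    component: int,
    domain: str = "scores",
    mesh: SurfaceMesh | None = None,
) -> float:
    """Pearson correlation between an aligned column and the template column.

    ``domain="scores"`` correlates over thalamic seeds; ``domain="loadings"``
    over cortical vertices (restricted to non-medial-wall vertices when a mesh
    is supplied). Returns NaN with a warning for constant columns.
    """
    if component >= aligned.k_align:
        raise ValueError(f"component {component} exceeds k_align={aligned.k_align}")
    if domain == "scores":
        a = aligned.aligned_scores[:, component]
        b = template.scores[:, component]
    elif domain == "loadings":
        a = aligned.aligned_loadings[:, component]
        b = template.loadings[:, component]
        if mesh is not None:
            a = a[mesh.cortex_mask]
            b = b[mesh.cortex_mask]
    else:
        raise ValueError("domain must be 'scores' or 'loadings'")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant column; similarity correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
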