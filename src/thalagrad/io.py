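"""Readers and writers for the pipeline's on-disk formats.

Connectivity matrices are MatrixMarket coordinate files (or dense CSV with a
vertex-id header row and a seed-id first column) with a JSON sidecar recording
seed/vertex identity and processing state. Surfaces are GIFTI: a white-matter
geometry, a spherical registration, and a label file for the medial wall.
Phenotypes and endpoint tables are TSV. All readers validate loudly; nothing
is silently coerced.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .core import PHENOTYPE_COLUMNS, CohortTable, ConnectivityMatrix
from .decomposition import Decomposition
from .surfaces import SurfaceMesh

__all__ = [
    "read_matrix", "write_matrix",
    "read_mesh", "write_mesh",
    "read_cohort", "write_cohort",
    "read_endpoints", "write_endpoints",
    "write_decomposition", "read_decomposition",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write a connectivity matrix as .mtx (sparse) or .csv (dense) + sidecar."""
    path = Path(path)
    if path.suffix == ".mtx":
        sio.mmwrite(str(path), sp.coo_matrix(matrix.values))
    elif path.suffix == ".csv":
        frame = pd.DataFrame(matrix.values, columns=[str(v) for v in matrix.vertex_ids])
        frame.insert(0, "seed_id", matrix.seed_ids)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported matrix format {path.suffix!r} (use .mtx or .csv)")
    _sidecar_path(path).write_text(json.dumps({
        "seed_ids": [int(s) if np.issubdtype(type(s), np.integer) else s
                     for s in matrix.seed_ids.tolist()],
        "vertex_ids": matrix.vertex_ids.tolist(),
        "state": matrix.state,
    }))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"matrix file {path} is missing or empty")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    if path.suffix == ".mtx":
        values = np.asarray(sio.mmread(str(path)).todense())
        if meta is None:
            raise ValueError(f"MatrixMarket file {path} requires its JSON sidecar")
        seed_ids = np.asarray(meta["seed_ids"])
        vertex_ids = np.asarray(meta["vertex_ids"])
        state = meta["state"]
    elif path.suffix == ".csv":
        frame = pd.read_csv(path)
        if "seed_id" not in frame.columns:
            raise ValueError(f"{path}: dense CSV must have a seed_id first column")
        dupes = frame["seed_id"].duplicated()
        if dupes.any():
            line = int(np.flatnonzero(dupes.to_numpy())[0]) + 2  # +header +1-based
            raise ValueError(f"{path}:{line}: duplicate seed id {frame['seed_id'][dupes].iloc[0]!r}")
        seed_ids = frame["seed_id"].to_numpy()
        vertex_ids = np.asarray([int(c) for c in frame.columns[1:]])
        values = frame.iloc[:, 1:].to_numpy(dtype=float)
        state = meta["state"] if meta else "raw"
    else:
        raise ValueError(f"unsupported matrix format {path.suffix!r}")
    if meta is not None and len(meta["seed_ids"]) != values.shape[0]:
        raise ValueError(
            f"{path}: sidecar lists {len(meta['seed_ids'])} seeds but matrix has {values.shape[0]} rows"
        )
    return ConnectivityMatrix(values, seed_ids, vertex_ids, state)


def _geometry_image(coords: np.ndarray, triangles: np.ndarray) -> nib.GiftiImage:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"))
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"))
    return img


def write_mesh(mesh: SurfaceMesh, white_path: str | Path, sphere_path: str | Path,
               label_path: str | Path | None = None) -> None:
    """Write white/sphere geometries and the medial-wall label as GIFTI."""
    nib.save(_geometry_image(mesh.white_coords, mesh.triangles), str(white_path))
    nib.save(_geometry_image(mesh.sphere_coords, mesh.triangles), str(sphere_path))
    if label_path is not None:
        img = nib.gifti.GiftiImage()
        img.add_gifti_data_array(nib.gifti.GiftiDataArray(
            mesh.medial_mask.astype(np.int32), intent="NIFTI_INTENT_LABEL"))
        table = nib.gifti.GiftiLabelTable()
        for key, name in ((0, "cortex"), (1, "medial_wall")):
            lab = nib.gifti.GiftiLabel(key=key)
            lab.label = name
            table.labels.append(lab)
        img.labeltable = table
        nib.save(img, str(label_path))


def _load_geometry(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    points = triangles = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            points = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            triangles = np.asarray(da.data, dtype=int)
    if points is None or triangles is None:
        raise ValueError(f"{path}: GIFTI geometry needs pointset and triangle arrays")
    return points, triangles


def read_mesh(white_path: str | Path, sphere_path: str | Path,
              label_path: str | Path | None = None) -> SurfaceMesh:
    """Assemble a SurfaceMesh from GIFTI geometry, sphere, and medial label."""
    white, tris = _load_geometry(Path(white_path))
    sphere, sphere_tris = _load_geometry(Path(sphere_path))
    if white.shape[0] != sphere.shape[0]:
        raise ValueError(
            f"vertex-count mismatch: white has {white.shape[0]}, sphere has {sphere.shape[0]}"
        )
    norms = np.linalg.norm(sphere, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("sphere coordinates deviate from unit norm; renormalizing")
    sphere = sphere / norms[:, np.newaxis]
    if label_path is not None and Path(label_path).exists():
        img = nib.load(str(label_path))
        medial = np.asarray(img.darrays[0].data).astype(bool)
        if medial.shape[0] != white.shape[0]:
            raise ValueError("medial-wall label vertex count does not match the geometry")
    else:
        warnings.warn("no medial-wall label supplied; assuming no medial wall")
        medial = np.zeros(white.shape[0], dtype=bool)
    return SurfaceMesh(white, sphere, tris, medial)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.loc[:, list(PHENOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"phenotype file {path} is missing or empty")
    return CohortTable(pd.read_csv(path, sep="\t"))


def write_endpoints(endpoints: pd.DataFrame, path: str | Path) -> None:
    endpoints.loc[:, ["seed_id", "x", "y", "z", "fa"]].to_csv(path, sep="\t", index=False)


def read_endpoints(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"endpoint file {path} is missing or empty")
    frame = pd.read_csv(path, sep="\t")
    missing = {"seed_id", "x", "y", "z", "fa"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: endpoint table missing columns {sorted(missing)}")
    return frame


def write_decomposition(dec: Decomposition, out_dir: str | Path, prefix: str,
                        seed_ids: np.ndarray | None = None,
                        vertex_ids: np.ndarray | None = None,
                        rotation: np.ndarray | None = None) -> None:
    """Serialize scores/loadings as TSV and scalars (+ optional rotation) as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = dec.k
    scores = pd.DataFrame(dec.scores, columns=[f"score_{j + 1}" for j in range(k)])
    scores.insert(0, "seed_id", seed_ids if seed_ids is not None else np.arange(len(scores)))
    scores.to_csv(out_dir / f"{prefix}_scores.tsv", sep="\t", index=False)
    loadings = pd.DataFrame(dec.loadings, columns=[f"loading_{j + 1}" for j in range(k)])
    loadings.insert(0, "vertex_id",
                    vertex_ids if vertex_ids is not None else np.arange(len(loadings)))
    loadings.to_csv(out_dir / f"{prefix}_loadings.tsv", sep="\t", index=False)
    meta = {
        "singular_values": dec.singular_values.tolist(),
        "variance_explained": dec.variance_explained.tolist(),
        "variance_fraction": dec.variance_fraction.tolist(),
    }
    if rotation is not None:
        meta["rotation"] = np.asarray(rotation).tolist()
    (out_dir / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def read_decomposition(in_dir: str | Path, prefix: str) -> Decomposition:
    """Load a decomposition serialized by :func:`write_decomposition`."""
    in_dir = Path(in_dir)
    scores_path = in_dir / f"{prefix}_scores.tsv"
    if not scores_path.exists():
        raise ValueError(f"no decomposition named {prefix!r} under {in_dir}")
    scores = pd.read_csv(scores_path, sep="\t").iloc[:, 1:].to_numpy(dtype=float)
    loadings = pd.read_csv(in_dir / f"{prefix}_loadings.tsv", sep="\t") \
        .iloc[:, 1:].to_numpy(dtype=float)
    meta = json.loads((in_dir / f"{prefix}_meta.json").read_text())
    return Decomposition(
        scores=scores,
        loadings=loadings,
        singular_values=np.asarray(meta["singular_values"]),
        variance_explained=np.asarray(meta["variance_explained"]),
        variance_fraction=np.asarray(meta["variance_fraction"]),
        column_means=np.zeros(loadings.shape[0]),
    )
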