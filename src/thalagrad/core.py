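"""Core containers shared across the pipeline stages.

Coordinate convention is RAS in millimetres: +x right (lateral), +y anterior,
+z superior. All serialized indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Processing states a connectivity matrix moves through, in pipeline order.
MATRIX_STATES = ("raw", "smoothed", "filtered", "normalized", "centred")

#: Required phenotype columns, in serialization order.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "scan_age_weeks",
    "birth_age_weeks",
    "sex",
    "group",
    "in_template",
)


@dataclass
class ConnectivityMatrix:
    """Seed-by-vertex structural connectivity weights.

    ``values`` is the dense matrix M (n seeds x m vertices). Raw, smoothed and
    filtered states hold non-negative streamline-weight sums; the normalized
    state lies in [0, 1]; the centred state has zero-mean columns.
    """

    values: np.ndarray
    seed_ids: np.ndarray
    vertex_ids: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.seed_ids = np.asarray(self.seed_ids)
        self.vertex_ids = np.asarray(self.vertex_ids)
        if self.values.ndim != 2:
            raise ValueError("connectivity values must be a 2-D array")
        if self.state not in MATRIX_STATES:
            raise ValueError(
                f"unknown matrix state {self.state!r}; expected one of {MATRIX_STATES}"
            )
        if self.values.shape != (len(self.seed_ids), len(self.vertex_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.seed_ids)} seed ids x {len(self.vertex_ids)} vertex ids"
            )
        if len(set(self.seed_ids.tolist())) != len(self.seed_ids):
            raise ValueError("duplicate seed ids")
        if self.state in ("raw", "smoothed", "filtered") and np.any(self.values < 0):
            raise ValueError(f"state={self.state} requires non-negative values")

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, state: str) -> "ConnectivityMatrix":
        """New matrix sharing seed/vertex identity with fresh values and state."""
        return ConnectivityMatrix(values, self.seed_ids, self.vertex_ids, state)

    def subset_seeds(self, indices: np.ndarray, state: str | None = None) -> "ConnectivityMatrix":
        indices = np.asarray(indices, dtype=int)
        return ConnectivityMatrix(
            self.values[indices], self.seed_ids[indices], self.vertex_ids,
            self.state if state is None else state,
        )


@dataclass
class CohortTable:
    """Per-subject phenotypes: scan age, birth age, sex, group, template flag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in phenotype table")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def scan_age(self) -> np.ndarray:
        return self.table["scan_age_weeks"].to_numpy(dtype=float)

    @property
    def group(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def term_mask(self) -> np.ndarray:
        return self.table["group"].to_numpy() == "term"


@dataclass
class SeedGrid:
    """Regular 3-D grid of tractography seed points inside an ellipsoidal mask.

    Emulates the study design of a ~1.75 mm seed lattice spanning the thalamic
    volume; coordinates are mm offsets from the ellipsoid centre.
    """

    coordinates: np.ndarray
    grid_spacing: float
    mask_shape: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("seed coordinates must be (n, 3)")

    @property
    def n_seeds(self) -> int:
        return self.coordinates.shape[0]

    @property
    def seed_ids(self) -> np.ndarray:
        return np.arange(self.n_seeds)
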