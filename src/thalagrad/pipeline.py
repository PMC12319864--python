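"""End-to-end pipeline driver: simulate -> build -> decompose -> infer.

A single :class:`PipelineConfig` (YAML-serializable) drives the full synthetic
workflow; :func:`run_pipeline` executes the stages in order, writes every
stage's outputs under the configured directory, and returns a
:class:`RunManifest` with a config snapshot, per-output checksums, and the
structured counts a reviewer needs (seeds retained, subjects aligned,
permutations run). Re-running an identical config reproduces bit-identical
stochastic outputs because every random stage derives from ``rng_seed``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectome, decomposition, inference, io, synthetic
from .core import ConnectivityMatrix

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    out_dir: str = "thalagrad_run"
    rng_seed: int = 0
    # synthetic cohort
    n_subjects: int = 50
    k_planted: int = 3
    mesh_level: int = 3
    grid_spacing: float = synthetic.DEFAULT_SPACING
    semi_axes: tuple[float, float, float] = synthetic.DEFAULT_SEMI_AXES
    age_range: tuple[float, float] = (29.0, 45.0)
    preterm_fraction: float = 0.0
    preterm_amplitude: float = 0.0
    # connectome build
    fwhm: float = 3.0
    epsilon: float = 0.01
    min_connected_vertices: int = 100
    # decomposition
    k: int = 5
    k_align: int = 5
    n_template: int = 20
    leave_one_out: bool = False
    # inference
    n_perm: int = 1000
    alpha: float = 0.05
    use_tfce: bool = True
    run_group_glm: bool = True

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 0 <= self.preterm_fraction <= 1:
            raise ValueError("preterm_fraction must lie in [0, 1]")
        if self.fwhm <= 0 or not 0 <= self.epsilon < 1:
            raise ValueError("invalid smoothing parameters")
        if self.k_align > self.k:
            raise ValueError("k_align cannot exceed k")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["semi_axes"] = list(data["semi_axes"])
        data["age_range"] = list(data["age_range"])
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["semi_axes"] = tuple(data.get("semi_axes", synthetic.DEFAULT_SEMI_AXES))
        data["age_range"] = tuple(data.get("age_range", (29.0, 45.0)))
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    counts: dict[str, float] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    log_path: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic workflow described by ``config``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__,
                           started=time.time())

    def record(path: Path) -> None:
        manifest.checksums[str(path.relative_to(out))] = _checksum(path)

    current_stage = "init"

    def stage(name: str) -> None:
        nonlocal current_stage
        current_stage = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        mesh = synthetic.make_sphere_mesh(config.mesh_level)
        grid = synthetic.make_seed_grid(config.grid_spacing, config.semi_axes)
        planted = synthetic.plant_structure(grid, mesh, config.k_planted,
                                            rng_seed=config.rng_seed)
        effect = None
        if config.preterm_amplitude != 0.0:
            effect = synthetic.make_preterm_offsets(
                mesh, (0.0, 1.0, 0.3), 25.0, config.preterm_amplitude
            ) + synthetic.make_preterm_offsets(
                mesh, (0.0, -1.0, 0.3), 25.0, -config.preterm_amplitude
            )
        cohort = synthetic.simulate_cohort(
            planted, config.n_subjects, config.age_range, config.preterm_fraction,
            preterm_effect=effect, rng_seed=config.rng_seed,
            template_size=config.n_template,
        )
        io.write_cohort(cohort.phenotypes, out / "phenotypes.tsv")
        record(out / "phenotypes.tsv")
        io.write_mesh(mesh, out / "white.surf.gii", out / "sphere.surf.gii",
                      out / "medialwall.label.gii")
        for name in ("white.surf.gii", "sphere.surf.gii", "medialwall.label.gii"):
            record(out / name)

        stage("build")
        kernel = connectome.build_kernel(mesh, config.fwhm, config.epsilon)
        smoothed = [connectome.smooth_connectome(m, kernel) for m in cohort.matrices]
        mean_matrix = smoothed[0].with_values(
            np.mean([m.values for m in smoothed], axis=0), state="smoothed")
        retained = connectome.filter_seeds(mean_matrix, config.min_connected_vertices)
        manifest.counts["seeds_retained"] = int(len(retained))
        filtered = [m.subset_seeds(retained, state="filtered") for m in smoothed]
        normalized = [connectome.normalize_sigmoid(m)[0] for m in filtered]
        io.write_matrix(normalized[0], out / "sub-000_normalized.mtx")
        record(out / "sub-000_normalized.mtx")

        stage("template")
        template = decomposition.build_template(
            normalized, cohort.phenotypes, config.n_template, config.k)
        io.write_decomposition(template.decomposition, out, "template",
                               seed_ids=grid.seed_ids[retained])
        record(out / "template_scores.tsv")
        record(out / "template_loadings.tsv")

        stage("align")
        ages = cohort.phenotypes.scan_age
        in_template = cohort.phenotypes.table["in_template"].to_numpy(dtype=bool)
        aligned, similarity = [], []
        for i, mat in enumerate(normalized):
            if config.leave_one_out:
                tmpl_i = decomposition.build_template(
                    normalized, cohort.phenotypes, config.n_template, config.k,
                    exclude_ids={cohort.phenotypes.subject_ids[i]},
                ).decomposition
            else:
                tmpl_i = template.decomposition
            dec = decomposition.decompose_normalized(mat, config.k)
            ali = decomposition.procrustes_align(dec, tmpl_i, config.k_align)
            aligned.append(ali)
            similarity.append(decomposition.similarity_to_template(
                ali, tmpl_i, component=0, domain="scores"))
        similarity = np.asarray(similarity)
        manifest.counts["subjects_aligned"] = len(aligned)
        np.savetxt(out / "similarity_pc1.tsv", similarity, header="similarity_pc1")
        record(out / "similarity_pc1.tsv")

        stage("age-maps")
        non_template = ~in_template
        r_sim_age = float(np.corrcoef(similarity[non_template], ages[non_template])[0, 1]) \
            if non_template.sum() >= 3 else float("nan")
        manifest.counts["similarity_age_r"] = r_sim_age
        score_stack = np.stack([a.aligned_scores[:, 0] for a in aligned])
        seed_map = inference.age_correlation_map(score_stack, ages, domain="thalamus",
                                                 q=config.alpha)
        seed_map.to_frame().to_csv(out / "age_map_seeds_pc1.tsv", sep="\t", index=False)
        record(out / "age_map_seeds_pc1.tsv")
        loading_stack = np.stack([a.aligned_loadings[:, 0] for a in aligned])
        vert_map = inference.age_correlation_map(loading_stack, ages, domain="cortex",
                                                 q=config.alpha)
        vert_map.to_frame().to_csv(out / "age_map_vertices_pc1.tsv", sep="\t", index=False)
        record(out / "age_map_vertices_pc1.tsv")

        if config.run_group_glm and config.preterm_fraction > 0:
            stage("group-glm")
            totals = np.stack([inference.vertex_totals(m) for m in filtered])
            design = inference.group_design(
                cohort.phenotypes.group, ages, cohort.phenotypes.table["sex"].to_numpy())
            fwer = inference.permutation_fwer(
                totals[:, mesh.cortex_mask], design, n_perm=config.n_perm,
                rng_seed=config.rng_seed + 1, use_tfce=config.use_tfce, mesh=mesh,
                alpha=config.alpha)
            manifest.counts["permutations_run"] = config.n_perm
            manifest.counts["fwer_significant_vertices"] = int(fwer.mask.sum())
            fwer.to_frame().to_csv(out / "group_glm.tsv", sep="\t", index=False)
            record(out / "group_glm.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {current_stage!r}: {exc}") from exc

    manifest.finished = time.time()
    config.to_yaml(out / "config.yaml")
    manifest.save(out / "manifest.json")
    return manifest
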