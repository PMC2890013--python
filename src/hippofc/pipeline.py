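"""End-to-end orchestration: simulate -> preprocess -> subject maps ->
group maps -> cluster tables -> asymmetry report, plus the volumetry
reproduction, driven by one validated configuration object.

Every stage logs its parameters and wall time, every artifact lands under
the output directory and is listed in the returned manifest, and a resolved
copy of the configuration is written alongside the outputs so any run can
be reproduced from its own records.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import connectivity, group, symmetry, volumetry
from .images import ROIMask, VolumeSeries
from .preprocessing import PreprocessConfig, preprocess
from .synthetic import (
    GroupSimSpec,
    ToyAtlasSpec,
    default_group_specs,
    make_toy_atlas,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_config", "load_config"]

logger = logging.getLogger("hippofc")

GROUP_PAIRS = [
    ("control", "right_mtle", "control_vs_right_mtle"),
    ("control", "left_mtle", "control_vs_left_mtle"),
    ("right_mtle", "left_mtle", "right_vs_left_mtle"),
]


@dataclass
class ConnectivityConfig:
    seed_sides: tuple[str, ...] = ("left", "right")
    z_method: str = "fisher_r"
    aggregation: str = "mean_z"
    hard_threshold: bool = False
    threshold_p: float = 1e-4

    def validate(self) -> list[str]:
        errors = []
        if not set(self.seed_sides) <= {"left", "right"}:
            errors.append(f"connectivity: seed_sides must be left/right, got {self.seed_sides}")
        if self.z_method not in ("fisher_r", "t_to_normal"):
            errors.append(f"connectivity: unknown z_method {self.z_method!r}")
        if self.aggregation not in ("mean_z", "concatenate"):
            errors.append(f"connectivity: unknown aggregation {self.aggregation!r}")
        if not 0 < self.threshold_p < 1:
            errors.append("connectivity: threshold_p must be in (0, 1)")
        return errors


@dataclass
class InferenceConfig:
    voxel_p: float = 0.001
    correction: str = "bonferroni"
    min_cluster_voxels: int = 125
    cluster_connectivity: int = 18
    display_t_intragroup: float = 15.0
    display_t_intergroup: float = 6.0

    def validate(self) -> list[str]:
        errors, warnings_ = [], []
        if not 0 < self.voxel_p < 1:
            errors.append("inference: voxel_p must be in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            errors.append(f"inference: unknown correction {self.correction!r}")
        if self.min_cluster_voxels < 0:
            errors.append("inference: min_cluster_voxels must be nonnegative")
        if self.cluster_connectivity not in (6, 18, 26):
            errors.append("inference: cluster_connectivity must be 6, 18 or 26")
        return errors

    def warnings(self) -> list[str]:
        out = []
        if self.min_cluster_voxels == 0:
            out.append("inference: min_cluster_voxels=0 disables the cluster-extent filter")
        return out


@dataclass
class SymmetryConfig:
    t_threshold: float = 6.0
    bin_width: float = 0.5

    def validate(self) -> list[str]:
        errors = []
        if self.bin_width <= 0:
            errors.append("symmetry: bin_width must be positive")
        return errors


@dataclass
class PipelineConfig:
    """Every stage's parameters plus the simulation geometry and seed."""

    atlas: ToyAtlasSpec = field(default_factory=ToyAtlasSpec)
    groups: list[GroupSimSpec] = field(default_factory=default_group_specs)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    symmetry: SymmetryConfig = field(default_factory=SymmetryConfig)
    rng_seed: int = 0
    run_volumetry: bool = True
    run_imaging: bool = True

    def __post_init__(self) -> None:
        # the pipeline-level seed is authoritative: every group's stream
        # descends from it (streams stay independent across groups because
        # the group label enters the per-run seed sequence)
        for g in self.groups:
            g.rng_seed = self.rng_seed

    def validate(self) -> tuple[list[str], list[str]]:
        """Return (errors, warnings) across every block."""
        errors = list(self.atlas.validate())
        tr = self.groups[0].tr_s if self.groups else None
        for spec in self.groups:
            errors += spec.validate(n_discard=self.preprocessing.n_discard)
        errors += self.preprocessing.validate(tr_s=tr)
        errors += self.connectivity.validate()
        errors += self.inference.validate()
        errors += self.symmetry.validate()
        return errors, self.inference.warnings()

    def resolve_seed(self, rng_seed: int | None = None) -> "PipelineConfig":
        if rng_seed is None:
            return self
        groups = [GroupSimSpec(**{**asdict(g), "rng_seed": rng_seed}) for g in self.groups]
        cfg = PipelineConfig(**{**self.__dict__, "groups": groups, "rng_seed": rng_seed})
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connectivity"]["seed_sides"] = list(self.connectivity.seed_sides)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "atlas" in d:
            a = dict(d["atlas"])
            if "grid_shape" in a:
                a["grid_shape"] = tuple(a["grid_shape"])
            if "roi_centers" in a:
                a["roi_centers"] = tuple(tuple(c) for c in a["roi_centers"])
            d["atlas"] = ToyAtlasSpec(**a)
        if "groups" in d:
            d["groups"] = [GroupSimSpec(**g) for g in d["groups"]]
        if "preprocessing" in d:
            d["preprocessing"] = PreprocessConfig(**d["preprocessing"])
        if "connectivity" in d:
            c = dict(d["connectivity"])
            if "seed_sides" in c:
                c["seed_sides"] = tuple(c["seed_sides"])
            d["connectivity"] = ConnectivityConfig(**c)
        if "inference" in d:
            d["inference"] = InferenceConfig(**d["inference"])
        if "symmetry" in d:
            d["symmetry"] = SymmetryConfig(**d["symmetry"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(payload)


def validate_config(config: PipelineConfig | str | Path) -> dict:
    """Validate a config (object or YAML path); report errors and warnings."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    errors, warnings_ = config.validate()
    return {"errors": errors, "warnings": warnings_, "ok": not errors}


def _log_stage(name: str, t0: float, **params) -> None:
    detail = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s elapsed=%.1fs %s", name, time.time() - t0, detail)


def run_pipeline(config: PipelineConfig | None = None, out_dir="hippofc_out",
                 rng_seed: int | None = None) -> dict:
    """Execute the full analysis; return a manifest of artifact paths.

    Stages: (optional) volumetry table statistics; cohort simulation; per
    run preprocessing; per-subject z maps for both seeds; 3 intragroup and
    3 intergroup t maps per seed; cluster tables; asymmetry report. Group
    t maps are written as NIfTI-1, tables as TSV, metadata as JSON, and the
    resolved configuration as YAML.
    """
    config = (config or PipelineConfig()).resolve_seed(rng_seed)
    errors, warnings_ = config.validate()
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    for w in warnings_:
        logger.warning(w)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"out_dir": str(out), "artifacts": {}, "stages": []}

    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    manifest["artifacts"]["config"] = "config_resolved.yaml"

    try:
        if config.run_volumetry:
            t0 = time.time()
            vol = volumetry.volumetry_report()
            vol.summary.to_csv(out / "volumetry_summary.tsv", sep="\t", index=False)
            vol.ipsilateral.to_csv(out / "volumetry_ipsilateral_t.tsv", sep="\t", index=False)
            vol.contralateral.to_csv(out / "volumetry_contralateral_t.tsv", sep="\t", index=False)
            (out / "volumetry_report.txt").write_text(vol.to_text() + "\n")
            npsy = volumetry.neuropsych_report()
            npsy.to_csv(out / "neuropsych_t.tsv", sep="\t", index=False)
            manifest["artifacts"]["volumetry"] = [
                "volumetry_summary.tsv", "volumetry_ipsilateral_t.tsv",
                "volumetry_contralateral_t.tsv", "volumetry_report.txt",
                "neuropsych_t.tsv",
            ]
            _log_stage("volumetry", t0)
            manifest["stages"].append("volumetry")

        if not config.run_imaging:
            return manifest

        t0 = time.time()
        atlas = make_toy_atlas(config.atlas)
        _log_stage("atlas", t0, grid=config.atlas.grid_shape,
                   brain_voxels=atlas.brain.n_voxels)

        # simulate + preprocess + subject maps, group by group
        t0 = time.time()
        subject_maps: dict[str, dict[str, list]] = {
            side: {} for side in config.connectivity.seed_sides
        }
        from .synthetic import simulate_subject  # local to keep import graph flat

        for spec in config.groups:
            for side in config.connectivity.seed_sides:
                subject_maps[side][spec.group_label] = []
            for subject_index in range(spec.n_subjects):
                runs = [preprocess(r, config.preprocessing)
                        for r in simulate_subject(atlas, spec, subject_index)]
                for side in config.connectivity.seed_sides:
                    smap = connectivity.subject_map(
                        runs, atlas.roi(side), brain_mask=atlas.brain,
                        z_method=config.connectivity.z_method,
                        aggregation=config.connectivity.aggregation,
                        hard_threshold=config.connectivity.hard_threshold,
                        threshold_p=config.connectivity.threshold_p,
                        seed_side=side,
                    )
                    subject_maps[side][spec.group_label].append(smap)
        _log_stage("subject_maps", t0,
                   subjects=sum(s.n_subjects for s in config.groups),
                   seeds=len(config.connectivity.seed_sides))

        # group statistics, cluster tables, symmetry
        t0 = time.time()
        group_maps: dict[tuple[str, str], group.GroupStatMap] = {}
        cluster_paths, map_paths = [], []
        for side in config.connectivity.seed_sides:
            for spec in config.groups:
                gmap = group.one_sample_map(
                    subject_maps[side][spec.group_label],
                    contrast=f"{spec.group_label}_mean",
                )
                gmap.report_t_threshold = config.inference.display_t_intragroup
                group_maps[(side, spec.group_label)] = gmap
            for ga, gb, name in GROUP_PAIRS:
                if ga not in subject_maps[side] or gb not in subject_maps[side]:
                    continue
                gmap = group.two_sample_map(
                    subject_maps[side][ga], subject_maps[side][gb], contrast=name,
                )
                gmap.report_t_threshold = config.inference.display_t_intergroup
                group_maps[(side, name)] = gmap

        voxel_volume = float(config.atlas.voxel_size_mm**3)
        for (side, name), gmap in group_maps.items():
            stem = f"tmap_{side}_seed_{name}"
            nib.save(nib.Nifti1Image(np.nan_to_num(gmap.t, posinf=1e10).astype(np.float32),
                                     gmap.affine), out / f"{stem}.nii.gz")
            map_paths.append(f"{stem}.nii.gz")
            supra, t_cut = group.voxel_threshold(
                gmap, p=config.inference.voxel_p,
                correction=config.inference.correction,
                brain_mask=atlas.brain.data,
            )
            table = group.cluster_filter(
                supra, gmap.t,
                min_cluster_voxels=config.inference.min_cluster_voxels,
                connectivity=config.inference.cluster_connectivity,
                voxel_volume_mm3=voxel_volume,
            )
            table = group.peak_report(table, gmap.affine)
            table.to_csv(out / f"clusters_{stem}.tsv", sep="\t", index=False)
            cluster_paths.append(f"clusters_{stem}.tsv")
            meta = dict(contrast=gmap.contrast, seed=side, df=gmap.df,
                        n_subjects=list(gmap.n_subjects),
                        voxel_p=config.inference.voxel_p,
                        correction=config.inference.correction, t_cutoff=t_cut,
                        min_cluster_voxels=config.inference.min_cluster_voxels,
                        cluster_connectivity=config.inference.cluster_connectivity,
                        report_t_threshold=gmap.report_t_threshold)
            with open(out / f"{stem}.json", "w") as fh:
                json.dump(meta, fh, indent=1)
        manifest["artifacts"]["group_maps"] = map_paths
        manifest["artifacts"]["cluster_tables"] = cluster_paths
        _log_stage("group_maps", t0, n_maps=len(group_maps))

        t0 = time.time()
        sym_inputs = {
            (side, name): group_maps[(side, name)]
            for side in config.connectivity.seed_sides
            for _, _, name in GROUP_PAIRS
            if (side, name) in group_maps
        }
        if {"left", "right"} <= set(config.connectivity.seed_sides):
            report = symmetry.asymmetry_summary(
                sym_inputs, t_threshold=config.symmetry.t_threshold,
                bin_width=config.symmetry.bin_width,
            )
            report.counts.to_csv(out / "symmetry_counts.tsv", sep="\t", index=False)
            report.ratios.to_csv(out / "symmetry_ratios.tsv", sep="\t", index=False)
            for (side, name), hist in report.histograms.items():
                hist.to_csv(out / f"histogram_{side}_{name}.tsv", sep="\t", index=False)
            (out / "symmetry_report.txt").write_text(report.to_text() + "\n")
            manifest["artifacts"]["symmetry"] = [
                "symmetry_counts.tsv", "symmetry_ratios.tsv", "symmetry_report.txt",
            ]
            manifest["ordering"] = report.ordering
            manifest["counts"] = {
                f"{seed}:{comp}": int(c)
                for seed, comp, c in report.counts.itertuples(index=False)
            }
        _log_stage("symmetry", t0)
        manifest["stages"] += ["subject_maps", "group_maps", "symmetry"]
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline failed during stage execution: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
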