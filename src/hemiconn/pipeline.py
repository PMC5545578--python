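"""End-to-end orchestration: config, staging, provenance manifest.

Two workflows are wired together:

* imaging: phantom (or user NIfTI tensors) -> symmetric parcellation ->
  deterministic tracking -> left/right FA-weighted networks -> metrics;
* cohort: simulated cohort of paired networks -> metric/AI tables ->
  statistical battery.

Every stage writes plain-text products into the output directory and the
run ends with a JSON provenance manifest (config hash, seeds, row counts,
output file hashes).  The manifest carries no timestamps, so reruns with
an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "save_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the standard printed values
    of the workflow (512 ROIs per hemisphere, FA stop 0.2, angle stop 45
    degrees, alpha = q = 0.05, 3 Bonferroni comparisons)."""

    n_rois: int = 512
    fa_stop: float = 0.2
    angle_stop: float = 45.0
    step_mm: float = None          # default: half the smallest voxel dim
    max_len_mm: float = 300.0
    edge_min_fibers: int = 1
    distance_rule: str = "inverse"
    alpha: float = 0.05
    q: float = 0.05
    bonferroni_m: int = 3
    seed: int = 0
    stages: tuple = ("simulate", "metrics", "stats")
    out_dir: str = "hemiconn_out"
    # imaging-branch inputs (optional)
    phantom: dict = None
    tensor_path: str = None
    mask_path: str = None
    # cohort-branch options
    cohort: dict = field(default_factory=dict)

    def __post_init__(self):
        # canonical (YAML-stable) representation so load(save(cfg)) == cfg
        def listify(v):
            if isinstance(v, (tuple, list)):
                return [listify(x) for x in v]
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            return v

        self.stages = tuple(self.stages)
        if self.phantom is not None:
            self.phantom = listify(self.phantom)
        self.cohort = listify(self.cohort)

    def validate(self) -> None:
        if not (0.0 < self.fa_stop < 1.0):
            raise ValueError(f"fa_stop={self.fa_stop} must lie in (0, 1)")
        if not (0.0 < self.angle_stop <= 90.0):
            raise ValueError(f"angle_stop={self.angle_stop} must lie in (0, 90]")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.edge_min_fibers < 1:
            raise ValueError("edge_min_fibers must be >= 1")
        if self.distance_rule not in ("inverse", "neglog"):
            raise ValueError(f"unknown distance_rule {self.distance_rule!r}")
        for p, name in ((self.alpha, "alpha"), (self.q, "q")):
            if not (0.0 < p < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        known = {"simulate", "parcellate", "track", "build-net", "metrics", "stats"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw.get("stages") is not None:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the provenance manifest."""
    from . import cohort as cohort_mod
    from . import metrics as metrics_mod
    from . import network as network_mod
    from . import parcellation, phantom as phantom_mod, tractography
    from .stats import BatteryConfig, battery_to_json, run_full_battery
    from .volume import BinaryMask, TensorVolume

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_sha256": _config_hash(config), "seed": config.seed,
                "stages": list(config.stages), "counts": {}, "outputs": {}}

    subjects = None
    cohort_df = None
    if "simulate" in config.stages:
        spec = cohort_mod.CohortSpec(**config.cohort, seed=config.seed) \
            if config.cohort else cohort_mod.CohortSpec(seed=config.seed)
        subjects, truth = cohort_mod.simulate_cohort(spec)
        cohort_mod.save_cohort(subjects, out / "cohort")
        cohort_df = cohort_mod.cohort_table(subjects)
        manifest["counts"]["subjects"] = len(subjects)
        manifest["counts"]["clip_rate"] = truth["clip_rate"]

    labels = None
    tensors = None
    if config.phantom is not None:
        bundles = tuple(
            phantom_mod.Bundle(points=tuple(map(tuple, b["points"])),
                               radius=b["radius"], fa=b["fa"])
            for b in config.phantom.get("bundles", ()))
        pspec = phantom_mod.PhantomSpec(
            grid_shape=tuple(config.phantom.get("grid_shape", (21, 11, 11))),
            voxel_size=tuple(config.phantom.get("voxel_size", (2.0, 2.0, 2.0))),
            bundles=bundles,
            background_fa=config.phantom.get("background_fa", 0.05),
            noise_sd=config.phantom.get("noise_sd", 0.0),
            seed=config.seed)
        tensors, _ = phantom_mod.make_tensor_phantom(pspec)
        tensors.save(out / "phantom_tensors.nii.gz")
        manifest["counts"]["phantom_voxels"] = int(np.prod(tensors.grid.shape))
    elif config.tensor_path is not None:
        tensors = TensorVolume.load(config.tensor_path, config.mask_path)

    if "parcellate" in config.stages:
        if tensors is None:
            raise ValueError("parcellate stage requires a phantom or tensor input")
        mask = BinaryMask(data=tensors.fa().data > 0.0, grid=tensors.grid)
        sym = parcellation.symmetrize_mask(mask)
        right = parcellation.random_partition(sym, "right", config.n_rois,
                                              config.seed)
        labels = parcellation.mirror_parcellation(right)
        labels.save(out / "template.nii.gz")
        labels.save_homolog_table(out / "homologs.tsv")
        manifest["counts"]["rois_per_hemisphere"] = config.n_rois

    streamlines = None
    if "track" in config.stages:
        if tensors is None:
            raise ValueError("track stage requires a phantom or tensor input")
        streamlines = tractography.fact_track(
            tensors, fa_stop=config.fa_stop, angle_stop=config.angle_stop,
            step=config.step_mm, max_len=config.max_len_mm)
        tractography.save_jsonl(streamlines, out / "streamlines.jsonl")
        manifest["counts"]["streamlines"] = sum(1 for s in streamlines
                                                if len(s) >= 2)

    nets = None
    if "build-net" in config.stages:
        if streamlines is None or labels is None:
            raise ValueError("build-net stage requires track and parcellate")
        fa = tensors.fa()
        nets = {}
        for hemi in ("left", "right"):
            net = network_mod.build_network(
                streamlines, labels, fa, hemi,
                edge_min_fibers=config.edge_min_fibers)
            network_mod.save_matrix(net.weights, out / f"weights_{hemi}.tsv")
            network_mod.save_matrix(net.counts, out / f"counts_{hemi}.tsv")
            nets[hemi] = net
        manifest["counts"]["edges_right"] = int((nets["right"].weights > 0).sum() // 2)

    if "metrics" in config.stages:
        if subjects is not None:
            triples = [(rec.id, l, r) for rec, l, r in subjects]
        elif nets is not None:
            triples = [("phantom", nets["left"].weights, nets["right"].weights)]
        else:
            raise ValueError("metrics stage has no networks to run on")
        mtab, atab = metrics_mod.cohort_metric_tables(
            triples, distance_rule=config.distance_rule)
        mtab.to_csv(out / "metrics.tsv", sep="\t", index=False)
        atab.to_csv(out / "ai.tsv", sep="\t", index=False)
        manifest["counts"]["metric_rows"] = len(mtab)
        manifest["counts"]["ai_rows"] = len(atab)

    if "stats" in config.stages:
        if cohort_df is None:
            raise ValueError("stats stage requires the simulate stage (cohort)")
        bc = BatteryConfig(alpha=config.alpha, q=config.q,
                           bonferroni_m=config.bonferroni_m)
        res = run_full_battery(mtab, atab, cohort_df, bc)
        blob = battery_to_json(res)
        with open(out / "battery.json", "w") as fh:
            json.dump(blob, fh, indent=1, sort_keys=True)
        manifest["counts"]["battery_tests"] = (
            len(res["within"]) + len(res["group"]) + len(res["associations"]))

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _file_hash(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
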