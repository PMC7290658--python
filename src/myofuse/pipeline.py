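"""End-to-end orchestration: simulate -> segment -> quantify -> DE classify.

``run_all`` takes a :class:`RunConfig` (usually loaded from YAML), simulates
the configured fields for each condition, runs the full imaging pipeline on
every field, compares the conditions, simulates and classifies a two-contrast
DE pair, and writes everything (plus a provenance record) into the output
directory.  All randomness derives from the single configured seed, so reruns
are byte-identical.
"""

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deg import DegThresholds, classify_opposing, filter_deg
from .degsim import DegSimParams, generate_deg_tables
from .errors import MissingInputError, ParameterError
from .fusion import build_fusion_report, compare_groups, roi_set_from_scene
from .io import (
    write_deg_table,
    write_image_stack,
    write_nucleus_set,
    write_roi_json,
    write_scene_json,
)
from .render import RenderParams, render_scene
from .scene import SceneParams, generate_scene, sampler_from_spec
from .segmentation import SegmentationConfig, segment_nuclei

logger = logging.getLogger("myofuse")

__all__ = ["ConditionSpec", "RunConfig", "run_all", "derive_seed"]

_SEED_MOD = 2 ** 31


def derive_seed(base: int, *indices: int) -> int:
    """Stable sub-seed derivation, always below 2^31."""
    h = hashlib.sha256(("/".join(map(str, (base, *indices)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % _SEED_MOD


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    n_fields: int = 3
    scene: dict = field(default_factory=dict)  # SceneParams overrides


@dataclass(frozen=True)
class RunConfig:
    conditions: tuple = ()
    render: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        conds = tuple(
            ConditionSpec(name=name, n_fields=int(spec.get("n_fields", 3)),
                          scene=dict(spec.get("scene", {})))
            for name, spec in d.get("conditions", {}).items()
        )
        return cls(
            conditions=conds,
            render=dict(d.get("render", {})),
            segmentation=dict(d.get("segmentation", {})),
            deg=dict(d.get("deg", {})),
            thresholds=dict(d.get("thresholds", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise MissingInputError(f"config not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "conditions": {c.name: {"n_fields": c.n_fields, "scene": c.scene}
                           for c in self.conditions},
            "render": self.render,
            "segmentation": self.segmentation,
            "deg": self.deg,
            "thresholds": self.thresholds,
            "seed": self.seed,
        }


def scene_params_from_overrides(overrides: dict, seed: int) -> SceneParams:
    kwargs = dict(overrides)
    if "nuclei_per_myotube_sampler" in kwargs:
        kwargs["nuclei_per_myotube_sampler"] = sampler_from_spec(
            kwargs["nuclei_per_myotube_sampler"])
    kwargs["seed"] = seed
    try:
        return SceneParams(**kwargs)
    except TypeError as exc:
        raise ParameterError(f"bad scene parameter: {exc}") from exc


def _params_from_overrides(cls, overrides: dict, **extra):
    try:
        return cls(**{**overrides, **extra})
    except TypeError as exc:
        raise ParameterError(f"bad {cls.__name__} parameter: {exc}") from exc


def run_all(config: RunConfig, out_dir) -> Path:
    """Execute the whole pipeline and write the report directory."""
    out = Path(out_dir)
    fields_dir = out / "fields"
    deg_dir = out / "deg"
    fields_dir.mkdir(parents=True, exist_ok=True)
    deg_dir.mkdir(parents=True, exist_ok=True)

    seg_config = _params_from_overrides(SegmentationConfig, config.segmentation)
    thresholds = _params_from_overrides(DegThresholds, config.thresholds)
    conditions = config.conditions or (ConditionSpec(name="control"),)

    manifest_rows = []
    per_condition: dict = {}
    for ci, cond in enumerate(conditions):
        metrics = {"total_nuclei": [], "differentiation_index": [],
                   "density": [], "myotube_counts": []}
        for fi in range(cond.n_fields):
            field_seed = derive_seed(config.seed, ci, fi)
            sp = scene_params_from_overrides(cond.scene, field_seed)
            scene = generate_scene(sp)
            rp = _params_from_overrides(RenderParams, config.render,
                                        seed=derive_seed(config.seed, ci, fi, 1))
            stack = render_scene(scene, rp)
            stem = f"{cond.name}_{fi:02d}"
            img_path = write_image_stack(stack, fields_dir / f"{stem}.tif")
            write_scene_json(scene, fields_dir / f"{stem}_scene.json")
            rois = roi_set_from_scene(scene)
            roi_path = write_roi_json(rois, fields_dir / f"{stem}_rois.json")
            nuclei = segment_nuclei(stack, seg_config)
            write_nucleus_set(nuclei, fields_dir / f"{stem}_nuclei.csv")
            report = build_fusion_report(nuclei, rois)
            (fields_dir / f"{stem}_report.json").write_text(
                json.dumps(report.to_dict(), sort_keys=True, indent=1))
            logger.info("field %s: %d nuclei, DI=%.3f", stem,
                        report.total_nuclei, report.differentiation_index)
            metrics["total_nuclei"].append(report.total_nuclei)
            metrics["differentiation_index"].append(report.differentiation_index)
            metrics["density"].append(report.nuclei_density_per_mm2)
            metrics["myotube_counts"].extend(report.myotube_counts)
            manifest_rows.append({"field_id": stem, "image": str(img_path.name),
                                  "rois": str(roi_path.name), "condition": cond.name})
        per_condition[cond.name] = metrics
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)

    # pairwise comparisons between the first two conditions (if present)
    comp_rows = []
    names = list(per_condition)
    if len(names) >= 2:
        a, b = per_condition[names[0]], per_condition[names[1]]
        pairs = [("total_nuclei", "student_t"),
                 ("differentiation_index", "student_t"),
                 ("density", "student_t"),
                 ("myotube_counts", "wilcoxon_rank_sum")]
        for metric, test in pairs:
            va, vb = a[metric], b[metric]
            if (test == "student_t" and (len(va) < 2 or len(vb) < 2)) or \
                    (test == "wilcoxon_rank_sum" and (len(va) < 1 or len(vb) < 1)):
                continue
            cmp = compare_groups(va, vb, test)
            comp_rows.append({"metric": metric, "test": cmp.test_name,
                              "statistic": cmp.statistic, "p_value": cmp.p_value,
                              "n_a": cmp.n_a, "n_b": cmp.n_b})
    pd.DataFrame(comp_rows, columns=["metric", "test", "statistic",
                                     "p_value", "n_a", "n_b"]).to_csv(
        out / "comparisons.csv", index=False)

    # DE stage
    deg_params = _params_from_overrides(DegSimParams, config.deg,
                                        seed=derive_seed(config.seed, 9999))
    table_a, table_b, labels = generate_deg_tables(deg_params)
    write_deg_table(table_a, deg_dir / "contrast_a.csv")
    write_deg_table(table_b, deg_dir / "contrast_b.csv")
    labels.to_csv(deg_dir / "planted_labels.csv", index=False)
    sig_a = filter_deg(table_a, thresholds)
    sig_b = filter_deg(table_b, thresholds)
    classification = classify_opposing(sig_a, sig_b)
    classification.table.to_csv(deg_dir / "classification.csv", index=False)
    (deg_dir / "summary.json").write_text(
        json.dumps(classification.to_summary_dict(), sort_keys=True, indent=1))
    logger.info("DE overlap %d, opposing %d", classification.overlap,
                classification.quadrant_counts["down_a_up_b"])

    config_dict = config.to_dict()
    config_json = json.dumps(config_dict, sort_keys=True, separators=(",", ":"))
    provenance = {
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {
            "myofuse": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=1))
    return out
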