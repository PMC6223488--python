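"""End-to-end orchestration: autocontouring, validation, and rating reports.

``run_autocontour`` composes the three algorithm steps for a test image
against an atlas of (image, contour-set) cases: projection-based rigid
registration, dual-force Demons deformable registration, contour
propagation through the resulting displacement fields, and STAPLE fusion
with the tissue-appearance model.  Registration of the atlas cases is
case-level independent — results do not depend on processing order — and
runs sequentially by default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fusion import FusionConfig, FusionResult, propagate_contours, staple_fuse
from .metrics import DEFAULT_MODIFIED, compare_structures, metrics_table
from .phantom import AtlasCase, read_atlas_dir
from .ratings import read_ratings_csv, score_distribution, summarize_agreement
from .registration import DemonsConfig, RigidConfig, register_demons, register_rigid_projections
from .volumes import DEFAULT_STRUCTURES, BinaryMask, ImageVolume, read_mask, write_mask

log = logging.getLogger("atlasseg")

__all__ = ["PipelineConfig", "RunRecord", "run_autocontour", "run_validation", "run_ratings"]


@dataclass
class PipelineConfig:
    """Configuration for the contouring pipeline and its reports."""

    structures: tuple[str, ...] = DEFAULT_STRUCTURES
    modified_structures: tuple[str, ...] = DEFAULT_MODIFIED
    rigid: RigidConfig = field(default_factory=RigidConfig)
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    # paired organs (eyes, parotids, cochleae, lungs) must keep both sides,
    # so the pipeline filters components by relative size, not "largest"
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig(component_filter="relative"))
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.structures:
            raise ValueError("structure list must be nonempty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("structures", "modified_structures", "output_dir", "seed"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key.endswith("structures") else raw[key]
        for key, klass in (("rigid", RigidConfig), ("demons", DemonsConfig),
                           ("fusion", FusionConfig)):
            if key in raw:
                kwargs[key] = klass(**raw[key])
        return cls(**kwargs)


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config snapshot, timings, diagnostics."""

    version: str
    config: dict
    stage_seconds: dict = field(default_factory=dict)
    fusion_diagnostics: dict = field(default_factory=dict)
    absent_structures: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)


def run_autocontour(
    test_image: ImageVolume,
    atlas: list[AtlasCase] | str | Path,
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, BinaryMask], RunRecord]:
    """Autocontour all configured structures on a test image.

    Each atlas case is registered to the test image (rigid then Demons);
    every structure's atlas contours are then propagated through the
    per-case displacement fields and fused with STAPLE.  A structure
    present in fewer than two atlas cases is reported absent.  The run is
    deterministic for fixed inputs and configuration.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(atlas, list):
        atlas = read_atlas_dir(atlas)
    if len(atlas) < 2:
        raise ValueError("autocontouring needs an atlas of >= 2 cases (fusion requires 2)")

    record = RunRecord(version=__version__, config=_config_dict(cfg))
    fields = []
    t0 = time.perf_counter()
    for case in atlas:
        log.info("registering atlas case %s", case.case_id)
        t1 = time.perf_counter()
        rigid = register_rigid_projections(test_image, case.image, cfg.rigid)
        fld = register_demons(test_image, case.image, rigid, cfg.demons)
        fields.append(fld)
        record.stage_seconds[f"register_{case.case_id}"] = time.perf_counter() - t1
    record.stage_seconds["registration_total"] = time.perf_counter() - t0

    from .volumes import RigidTransform3D

    identity = RigidTransform3D.identity()
    contours: dict[str, BinaryMask] = {}
    t0 = time.perf_counter()
    for name in cfg.structures:
        masks = [case.masks.get(name) for case in atlas]
        propagated, missing = propagate_contours(
            masks, [identity] * len(atlas), fields, structure_name=name
        )
        # a propagated contour that landed empty carries no rating either
        missing = [
            miss or prop.is_empty() for prop, miss in zip(propagated, missing)
        ]
        n_avail = sum(not m for m in missing)
        if n_avail < 2:
            log.warning("structure %s present in %d atlas case(s); reported absent",
                        name, n_avail)
            record.absent_structures.append(name)
            continue
        result: FusionResult = staple_fuse(propagated, test_image, cfg.fusion, missing=missing)
        contours[name] = result.fused_mask
        record.fusion_diagnostics[name] = {
            "sensitivities": result.sensitivities.tolist(),
            "specificities": result.specificities.tolist(),
            "iterations": result.iterations,
            "log_likelihood_first_last": [result.log_likelihood[0], result.log_likelihood[-1]],
            "n_inputs": n_avail,
        }
    record.stage_seconds["fusion_total"] = time.perf_counter() - t0

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, mask in contours.items():
            write_mask(mask, out / f"auto_{name}.nii")
        (out / "run_record.json").write_text(record.to_json())
    return contours, record


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _load_mask_dir(path: Path, prefix: str) -> dict[str, BinaryMask]:
    masks = {}
    for f in sorted(path.glob(f"{prefix}*.nii")):
        name = f.stem[len(prefix):]
        masks[name] = read_mask(f, name)
    return masks


def run_validation(
    auto_sets: dict[str, dict[str, BinaryMask]],
    reference_sets: dict[str, dict[str, BinaryMask]],
    cfg: PipelineConfig | None = None,
):
    """Compare autocontours with reference contours across cases.

    ``auto_sets`` and ``reference_sets`` map case id -> {structure: mask}.
    Returns ``(per_case_table, summary)`` where the summary aggregates
    mean +/- SD (and median/IQR) per structure and the fraction of
    structures left unedited (identical to the reference).
    """
    cfg = cfg or PipelineConfig()
    case_ids = sorted(set(auto_sets) & set(reference_sets))
    if not case_ids:
        raise ValueError("no paired cases to validate")
    tables = []
    for cid in case_ids:
        ms = compare_structures(auto_sets[cid], reference_sets[cid], cfg.modified_structures)
        t = metrics_table(ms)
        t.insert(0, "case_id", cid)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    present = table[~table["absent"]]
    if len(present) == 0:
        raise ValueError("no paired structures found in any case")

    summary: dict = {"n_cases": len(case_ids), "per_structure": {}}
    for name, grp in present.groupby("structure"):
        entry = {}
        for col in ("dsc", "msd_mm", "hd_mm", "hd_directed_mm",
                    "modified_dsc", "modified_msd_mm", "modified_hd_mm"):
            vals = grp[col].dropna().astype(float)
            if len(vals) == 0:
                continue
            entry[col] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "median": float(vals.median()),
                "iqr": [float(vals.quantile(0.25)), float(vals.quantile(0.75))],
            }
        entry["fraction_unedited"] = float((~grp["edited"]).mean())
        summary["per_structure"][name] = entry
    summary["fraction_unedited_overall"] = float((~present["edited"]).mean())
    return table, summary


def run_validation_dirs(auto_dir, reference_dir, cfg: PipelineConfig | None = None):
    """Directory-based validation: one subdirectory per case, masks named
    ``auto_<structure>.nii`` / ``mask_<structure>.nii`` (flat layouts with a
    single case are accepted too)."""
    auto_dir, reference_dir = Path(auto_dir), Path(reference_dir)

    def load(root, prefix):
        subdirs = [d for d in sorted(root.iterdir()) if d.is_dir()]
        if subdirs:
            return {d.name: _load_mask_dir(d, prefix) for d in subdirs}
        return {"case000": _load_mask_dir(root, prefix)}

    auto_sets = load(auto_dir, "auto_")
    if not any(auto_sets.values()):
        auto_sets = load(auto_dir, "mask_")
    ref_sets = load(reference_dir, "mask_")
    auto_sets = {k: v for k, v in auto_sets.items() if v}
    ref_sets = {k: v for k, v in ref_sets.items() if v}
    return run_validation(auto_sets, ref_sets, cfg)


def run_ratings(ratings_csv, cfg: PipelineConfig | None = None) -> dict:
    """Agreement categorization and score distribution from a rating CSV."""
    df = read_ratings_csv(ratings_csv)
    if len(df) == 0:
        raise ValueError(f"{ratings_csv}: no rating rows")
    return {
        "agreement": summarize_agreement(df),
        "distribution": score_distribution(df),
    }
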