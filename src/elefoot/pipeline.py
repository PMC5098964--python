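"""End-to-end orchestration: simulate -> segment -> register -> roi -> cop -> summarize.

Every stage communicates through written artifacts (records, step files,
transform JSON, CSV tables), so the pipeline is restartable and auditable.
A manifest records the configuration, its hash, the seed and the package
version; rerunning with the same configuration and seed reproduces every
output file byte-identically.

The single top-level seed fans out to per-stage, per-item child seeds by
stable hashing of stage names (CRC32), so a stage rerun in isolation sees
the same random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from elefoot import __version__
from elefoot.cop import (
    DEFAULT_PAIRS,
    compare_feet,
    cop_trajectory,
    mean_trajectory,
    time_normalize,
)
from elefoot.errors import DigitizationError, SelectionError
from elefoot.pressure_io import (
    PlateSpec,
    PressureRecord,
    TrialMeta,
    write_pressure_record,
)
from elefoot.register import (
    RigidTransform2D,
    apply_transform,
    apply_transform_to_series,
    peak_pressure_image,
    register_to_template,
    select_template,
)
from elefoot.roi import digitize_rois, mean_image, sensitivity_table
from elefoot.segment import (
    SegmentationConfig,
    assess_completeness,
    classify_feet,
    segment_steps,
)
from elefoot.stats import froude, summarize, weighted_mean
from elefoot.synthetic import (
    Footfall,
    GaitPlan,
    default_foot_models,
    default_gait_plan,
    generate_trial,
)

log = logging.getLogger("elefoot.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class SimulateConfig:
    n_trials: int = 3
    noise_sd_kpa: float = 1.0
    speed_ms: float = 1.2
    stance_s: float = 0.8
    subject_id: str = "SYN1"
    body_mass_kg: float = 2300.0
    hip_height_m: float = 1.85
    placement_jitter_m: float = 0.01
    heading_jitter_deg: float = 4.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    out_dir: str = "elefoot_out"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration_mode: str = "auto"  # "auto" | "identity"
    roi_source: str = "auto"  # "auto" | path to a manual ROI CSV
    n_points: int = 101
    cop_threshold_kpa: float = 5.0
    pairs: tuple[str, ...] = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        if self.registration_mode not in ("auto", "identity"):
            raise ValueError("registration_mode must be 'auto' or 'identity'")
        if self.n_points < 2:
            raise ValueError("n_points must be at least 2")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a plain mapping (YAML/JSON), rejecting unknown keys."""
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "simulate" in raw:
            sub = dict(raw["simulate"])
            bad = set(sub) - {f.name for f in dataclasses.fields(SimulateConfig)}
            if bad:
                raise ValueError(f"unknown simulate keys: {sorted(bad)}")
            raw["simulate"] = SimulateConfig(**sub)
        if "segmentation" in raw:
            sub = dict(raw["segmentation"])
            bad = set(sub) - {f.name for f in dataclasses.fields(SegmentationConfig)}
            if bad:
                raise ValueError(f"unknown segmentation keys: {sorted(bad)}")
            raw["segmentation"] = SegmentationConfig(**sub)
        if "pairs" in raw:
            raw["pairs"] = tuple(raw["pairs"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def child_seed(seed: int, stage: str, item: int = 0) -> int:
    """Stable per-stage child seed below 2**31."""
    return zlib.crc32(f"{seed}:{stage}:{item}".encode()) & 0x7FFFFFFF


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jittered_plan(cfg: SimulateConfig, trial: int, seed: int) -> GaitPlan:
    """Default gait plan with per-trial placement jitter."""
    rng = np.random.default_rng(child_seed(seed, "simulate", trial))
    base = default_gait_plan(
        seed=child_seed(seed, "noise", trial),
        noise_sd_kpa=cfg.noise_sd_kpa,
        stance_s=cfg.stance_s,
        speed_ms=cfg.speed_ms,
    )
    seq = tuple(
        Footfall(
            label=f.label,
            x_m=f.x_m + rng.uniform(-cfg.placement_jitter_m, cfg.placement_jitter_m),
            y_m=f.y_m + rng.uniform(-cfg.placement_jitter_m, cfg.placement_jitter_m),
            onset_s=f.onset_s,
            heading_deg=f.heading_deg
            + rng.uniform(-cfg.heading_jitter_deg, cfg.heading_jitter_deg),
        )
        for f in base.step_sequence
    )
    return dataclasses.replace(base, step_sequence=seq)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all stages on a synthetic cohort; return the result bundle.

    The bundle maps artifact names to DataFrames (step summary, ROI table,
    COP table, comparison table, subject and cohort summaries) and includes
    the manifest dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    models = default_foot_models()
    meta = TrialMeta(
        subject_id=sim.subject_id,
        body_mass_kg=sim.body_mass_kg,
        hip_height_m=sim.hip_height_m,
        velocity_ms=sim.speed_ms,
        side_hint="+y",
    )

    # ---- simulate ----------------------------------------------------
    records: list[PressureRecord] = []
    for trial in range(sim.n_trials):
        plan = _jittered_plan(sim, trial, config.seed)
        record, _truth = generate_trial(models, plan, meta=meta)
        records.append(record)
        write_pressure_record(record, out / f"trial{trial:03d}")
        log.info("simulate trial=%d frames=%d", trial, record.n_frames)

    # ---- segment + classify ------------------------------------------
    steps_by_foot: dict[str, list[tuple[int, Any]]] = {}
    step_rows = []
    for trial, record in enumerate(records):
        steps = segment_steps(record, config.segmentation)
        for s in steps:
            s.complete_spatial, s.complete_temporal = assess_completeness(
                s, record, config.segmentation
            )
        steps = classify_feet(steps, record.meta)
        for i, s in enumerate(steps):
            step_rows.append(
                {
                    "trial": trial,
                    "step_id": f"t{trial}s{i}",
                    "onset_s": s.onset_s,
                    "duration_s": s.duration_s,
                    "label": s.foot_label,
                    "complete_spatial": s.complete_spatial,
                    "complete_temporal": s.complete_temporal,
                    "n_voxels": s.n_voxels,
                }
            )
            log.info(
                "segment trial=%d step=%d label=%s voxels=%d", trial, i, s.foot_label, s.n_voxels
            )
            if s.foot_label == "unknown":
                continue
            steps_by_foot.setdefault(s.foot_label, []).append((trial, s))
    steps_summary = pd.DataFrame(step_rows)
    steps_summary.to_csv(out / "steps_summary.csv", index=False)

    # ---- register -----------------------------------------------------
    registered: dict[str, list[tuple[int, Any]]] = {}
    mean_images = {}
    templates = {}
    transform_rows = []
    for label, items in sorted(steps_by_foot.items()):
        imgs = [peak_pressure_image(s, label) for _, s in items]
        flags = [(bool(s.complete_spatial), bool(s.complete_temporal)) for _, s in items]
        try:
            template = select_template(imgs, flags)
        except SelectionError:
            log.warning("no complete template for foot %s; foot skipped", label)
            continue
        templates[label] = template
        reg_imgs = []
        reg_steps = []
        for (trial, s), img in zip(items, imgs):
            if config.registration_mode == "auto" and img is not template.image:
                tf = register_to_template(img, template)
            else:
                tf = RigidTransform2D()
            transform_rows.append(
                {
                    "foot": label,
                    "trial": trial,
                    "dx_cells": tf.dx_cells,
                    "dy_cells": tf.dy_cells,
                    "theta_deg": tf.theta_deg,
                }
            )
            reg_imgs.append(apply_transform(img, tf, centre_rc=img.active_centroid()))
            reg_steps.append((trial, apply_transform_to_series(s, tf)))
        registered[label] = reg_steps
        mean_images[label] = mean_image(reg_imgs)
    pd.DataFrame(transform_rows).to_csv(out / "transforms.csv", index=False)
    with open(out / "transforms.json", "w") as fh:
        json.dump(transform_rows, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # ---- roi ----------------------------------------------------------
    roi_frames = []
    for label, mimg in sorted(mean_images.items()):
        try:
            rois = digitize_rois(
                dataclasses.replace(templates[label], image=mimg), mode="auto"
            )
        except DigitizationError as exc:
            log.warning("auto digitization failed for %s: %s", label, exc)
            continue
        for trial, s in registered[label]:
            img = peak_pressure_image(s, label)
            roi_frames.append(
                sensitivity_table(
                    img,
                    rois,
                    subject=sim.subject_id,
                    trial=str(trial),
                    step=f"t{trial}-{label}",
                )
            )
    roi_table = (
        pd.concat(roi_frames, ignore_index=True) if roi_frames else pd.DataFrame()
    )
    roi_table.to_csv(out / "roi_table.csv", index=False)

    # ---- cop ----------------------------------------------------------
    cop_rows = []
    mean_trajs = {}
    for label, reg_steps in sorted(registered.items()):
        trajs = []
        for trial, s in reg_steps:
            traj = cop_trajectory(s, config.cop_threshold_kpa)
            for i in range(len(traj)):
                cop_rows.append(
                    {
                        "step_id": f"t{trial}-{label}",
                        "frame": i,
                        "x_m": traj.points[i, 0],
                        "y_m": traj.points[i, 1],
                        "p_total_kpa": float(traj.total_force_proxy[i]),
                    }
                )
            trajs.append(time_normalize(traj, config.n_points))
        if trajs:
            mean_trajs[label] = mean_trajectory(trajs)
    pd.DataFrame(
        cop_rows, columns=["step_id", "frame", "x_m", "y_m", "p_total_kpa"]
    ).to_csv(out / "cop_table.csv", index=False)

    pairs = [
        p
        for p in config.pairs
        if all(name in mean_trajs for name in p.split("-"))
    ]
    skipped = [p for p in config.pairs if p not in pairs]
    if skipped:
        log.warning("pairs skipped for missing feet: %s", skipped)
    comparisons = (
        compare_feet(mean_trajs, pairs) if pairs else pd.DataFrame()
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)

    # ---- summarize -----------------------------------------------------
    subject_rows = []
    for label, reg_steps in sorted(registered.items()):
        maxima = np.array(
            [float(peak_pressure_image(s, label).values.max()) for _, s in reg_steps]
        )
        subject_rows.append(
            {
                "subject": sim.subject_id,
                "foot": label,
                "mean_max_pressure_kpa": float(maxima.mean()),
                "se_max_pressure_kpa": float(
                    maxima.std(ddof=1) / np.sqrt(len(maxima)) if len(maxima) > 1 else 0.0
                ),
                "n_steps": len(maxima),
                "n_trials": sim.n_trials,
                "velocity_ms": sim.speed_ms,
                "froude": froude(sim.speed_ms, sim.hip_height_m),
            }
        )
    subject_summary = pd.DataFrame(subject_rows)
    subject_summary.to_csv(out / "subject_summary.csv", index=False)

    if not roi_table.empty:
        # mean over the five placement positions first, then summaries
        per_step = (
            roi_table.groupby(["subject", "foot", "step", "roi"])["peak_pressure_kpa"]
            .mean()
            .reset_index()
        )
        roi_summary = summarize(per_step, ["foot", "roi"])
        cohort = {
            "grand_mean_kpa": float(per_step["peak_pressure_kpa"].mean()),
            "fore_mean_kpa": float(
                per_step[per_step["foot"].str.startswith("F")]["peak_pressure_kpa"].mean()
            ),
            "hind_mean_kpa": float(
                per_step[per_step["foot"].str.startswith("H")]["peak_pressure_kpa"].mean()
            ),
            "mean_speed_ms": sim.speed_ms,
            "froude": froude(sim.speed_ms, sim.hip_height_m),
            "step_weighted_mass_kg": weighted_mean(
                [sim.body_mass_kg], [len(step_rows)]
            ),
        }
    else:
        roi_summary = pd.DataFrame()
        cohort = {}
    roi_summary.to_csv(out / "roi_summary.csv", index=False)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(cohort, fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "subject_summary": subject_summary,
        "steps_summary": steps_summary,
        "roi_table": roi_table,
        "roi_summary": roi_summary,
        "cop_table": pd.DataFrame(cop_rows),
        "comparisons": comparisons,
        "cohort_summary": cohort,
        "mean_trajectories": mean_trajs,
        "manifest": manifest,
    }
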