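"""Batch pipeline: calibrate -> correct -> segment -> quantify -> average.

A :class:`RunManifest` lists conditions (species combination x time point),
each with replicate stack files, plus single-label control stacks for
crosstalk calibration. ``run_pipeline`` executes every condition
independently — one failed condition is reported and does not abort the
others — and writes per-slice profile, composition and replicate-summary
CSV tables plus a JSON run report recording versions, seeds, thresholds,
the crosstalk matrix, overlap fractions and warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crosstalk import CrosstalkMatrix, build_crosstalk_matrix, correct_stack
from .io import ExperimentConfig, read_stack
from .quantify import average_replicates, composition, slice_profile
from .segmentation import segment_channel

logger = logging.getLogger("biofilmvol")


@dataclass
class Replicate:
    replicate_id: str
    path: str


@dataclass
class Condition:
    name: str
    time_label: str
    replicates: list[Replicate]

    def __post_init__(self) -> None:
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate replicate ids in condition {self.name!r}")


@dataclass
class RunManifest:
    conditions: list[Condition]
    controls: dict[str, str] = field(default_factory=dict)  # label -> path
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        conditions = [
            Condition(
                name=c["name"],
                time_label=str(c.get("time", "")),
                replicates=[
                    Replicate(str(r["id"]), r["path"]) for r in c["replicates"]
                ],
            )
            for c in data.get("conditions", [])
        ]
        return cls(
            conditions=conditions,
            controls={str(k): str(v) for k, v in (data.get("controls") or {}).items()},
            output_dir=str(data.get("output_dir", ".")),
            seed=int(data.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        missing = [
            r.path
            for c in self.conditions
            for r in c.replicates
            if not Path(r.path).exists()
        ]
        missing += [p for p in self.controls.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing file(s): {missing}")


def analyze_stack(stack, crosstalk: CrosstalkMatrix, config: ExperimentConfig):
    """Correct, segment and quantify one in-memory stack.

    Returns ``(masks, composition_summary, slice_profiles)`` — the
    per-replicate core of the batch pipeline, usable directly on stacks that
    never touch disk. Empty-channel warnings propagate to the caller.
    """
    corrected = correct_stack(stack, crosstalk, method=config.crosstalk_method)
    masks = [
        segment_channel(corrected, lab, sigma=config.blur_sigma, tol=config.li_tol)
        for lab in config.channel_labels
    ]
    comp = composition(masks)
    profiles = [slice_profile(m, config.voxel_size) for m in masks]
    return masks, comp, profiles


def run_pipeline(
    manifest: RunManifest,
    config: ExperimentConfig,
    crosstalk: CrosstalkMatrix | None = None,
) -> dict:
    """Execute the full quantification over a manifest.

    Returns the run report (also written to ``report.json``); raises
    ``RuntimeError`` at the end if any condition failed.
    """
    from . import __version__

    manifest.validate_paths()
    out_dir = Path(manifest.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if crosstalk is None:
        if not manifest.controls:
            raise ValueError(
                "manifest has no controls and no precomputed crosstalk matrix"
            )
        controls = {
            lab: read_stack(path, config) for lab, path in manifest.controls.items()
        }
        crosstalk = build_crosstalk_matrix(controls, config)
    crosstalk.to_dataframe().to_csv(out_dir / "crosstalk_matrix.csv")

    profile_rows: list[dict] = []
    composition_rows: list[dict] = []
    summary_rows: list[dict] = []
    report: dict = {
        "tool": "biofilmvol",
        "version": __version__,
        "seed": manifest.seed,
        "config": {
            "blur_sigma": list(config.blur_sigma),
            "crosstalk_method": config.crosstalk_method,
            "ratio_clip": list(config.ratio_clip),
            "ratio_bins": config.ratio_bins,
            "background_subtract": config.background_subtract,
        },
        "crosstalk_matrix": {
            "labels": crosstalk.labels,
            "k": crosstalk.k.tolist(),
        },
        "conditions": {},
        "failed": [],
    }

    for cond in manifest.conditions:
        try:
            cond_report = _run_condition(
                cond, config, crosstalk, profile_rows, composition_rows, summary_rows
            )
            report["conditions"][cond.name] = cond_report
        except Exception as exc:  # keep other conditions running
            logger.error("condition %s failed: %s", cond.name, exc)
            report["failed"].append({"condition": cond.name, "error": str(exc)})

    pd.DataFrame(profile_rows).to_csv(out_dir / "slice_profiles.csv", index=False)
    pd.DataFrame(composition_rows).to_csv(out_dir / "composition.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out_dir / "replicate_summary.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if report["failed"]:
        raise RuntimeError(
            f"{len(report['failed'])} condition(s) failed: "
            + ", ".join(f["condition"] for f in report["failed"])
        )
    return report


def _run_condition(
    cond: Condition,
    config: ExperimentConfig,
    crosstalk: CrosstalkMatrix,
    profile_rows: list,
    composition_rows: list,
    summary_rows: list,
) -> dict:
    cond_report: dict = {"time": cond.time_label, "replicates": {}, "warnings": []}
    profiles_by_channel: dict[str, list] = {lab: [] for lab in config.channel_labels}

    for rep in cond.replicates:
        stack = read_stack(rep.path, config)
        corrected = correct_stack(stack, crosstalk, method=config.crosstalk_method)
        masks = []
        thresholds = {}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for lab in config.channel_labels:
                mask = segment_channel(
                    corrected, lab, sigma=config.blur_sigma, tol=config.li_tol
                )
                masks.append(mask)
                thresholds[lab] = mask.threshold
        for w in caught:
            cond_report["warnings"].append(f"{rep.replicate_id}: {w.message}")

        comp = composition(masks)
        for mask in masks:
            prof = slice_profile(mask, config.voxel_size)
            profiles_by_channel[mask.channel].append(prof)
            for z, f_z in enumerate(prof.fractions):
                profile_rows.append(
                    {
                        "condition": cond.name,
                        "time": cond.time_label,
                        "replicate": rep.replicate_id,
                        "channel": mask.channel,
                        "z": z,
                        "fraction": f_z,
                    }
                )
        for lab, share in zip(comp.labels, comp.shares_percent):
            composition_rows.append(
                {
                    "condition": cond.name,
                    "time": cond.time_label,
                    "replicate": rep.replicate_id,
                    "channel": lab,
                    "share_percent": share,
                }
            )
        cond_report["replicates"][rep.replicate_id] = {
            "thresholds": thresholds,
            "shares_percent": dict(
                zip(comp.labels, np.round(comp.shares_percent, 6).tolist())
            ),
            "overlap_fraction": comp.overlap_fraction,
        }
        if comp.overlap_fraction > 0.05:
            cond_report["warnings"].append(
                f"{rep.replicate_id}: channel overlap fraction "
                f"{comp.overlap_fraction:.3f}"
            )

    for lab, profs in profiles_by_channel.items():
        if len(profs) < 2:
            continue
        summary = average_replicates(profs)
        summary_rows.append(
            {
                "condition": cond.name,
                "time": cond.time_label,
                "channel": lab,
                "n": summary.n,
                "mean_total_fraction": summary.mean_total,
                "sd_total_fraction": summary.sd_total,
            }
        )
        cond_report.setdefault("summary", {})[lab] = {
            "n": summary.n,
            "mean_total_fraction": summary.mean_total,
            "sd_total_fraction": summary.sd_total,
        }
    return cond_report
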