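"""End-to-end orchestration of the five-step stitching pipeline.

Steps: (1) load the four input series, (2) localize the landmarks (from a
configuration file or by automatic BB detection), (3) split the lower
segment into legs, solve the per-leg transform and resample, (4) apply the
decay correction and the DICOM tag edits, (5) write the stitched whole-body
CT and PET series plus a machine-readable run report.

The report records every resolved parameter (landmarks, correspondence
permutations, congruence residuals, decay factor, stitching plane, output
geometry and all warnings), which is sufficient to reproduce the run.
Inputs are never modified; outputs are only written after every computation
has succeeded, so a failing stage leaves no partial output.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import decay as _decay
from . import dicom_io, geometry, resample, segmentation
from .dicom_io import VolumeGrid
from .geometry import LandmarkSet
from .phantom import PhantomSpec, generate_phantom

__all__ = ["PipelineError", "run_stitch", "generate_fixture"]

logger = logging.getLogger("petstitch")

SIDES = ("left", "right")
SEGMENTS = ("upper", "lower")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    """Context manager that re-raises module errors with the stage named."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _landmarks_from_config(cfg, ct_grids: dict[str, VolumeGrid]) -> dict[str, dict[str, LandmarkSet]]:
    """Parse landmarks given per leg, per segment, as mm or CT voxel indices."""
    if isinstance(cfg, (str, Path)):
        with open(cfg) as fh:
            cfg = yaml.safe_load(fh)
    units = cfg.get("units", "mm")
    if units not in ("mm", "voxel"):
        raise ValueError(f"landmark units must be 'mm' or 'voxel', got {units!r}")
    out: dict[str, dict[str, LandmarkSet]] = {}
    for side in SIDES:
        out[side] = {}
        for segment in SEGMENTS:
            entry = cfg[side][segment]
            pts = np.array([entry[label] for label in ("a", "b", "c")], dtype=float)
            if units == "voxel":
                pts = ct_grids[segment].voxel_to_patient(pts)
            out[side][segment] = LandmarkSet(points=pts, side=side, segment=segment)
    return out


def _landmarks_auto(
    ct_grids: dict[str, VolumeGrid],
    partitions: dict[str, segmentation.LegPartition],
    detection_cfg: dict,
) -> dict[str, dict[str, LandmarkSet]]:
    """Detect six BBs per segment and assign them to legs via the leg split."""
    out: dict[str, dict[str, LandmarkSet]] = {s: {} for s in SIDES}
    for segment in SEGMENTS:
        cands = segmentation.detect_bbs(
            ct_grids[segment], expected_count=6, **detection_cfg
        )
        groups: dict[str, list[np.ndarray]] = {"left": [], "right": []}
        for cand in cands:
            groups[str(partitions[segment].side_of(cand.center))].append(cand.center)
        for side in SIDES:
            if len(groups[side]) != 3:
                raise segmentation.BBDetectionError(
                    f"{segment} segment: found {len(groups[side])} BBs on the "
                    f"{side} leg, need exactly 3; specify landmarks manually"
                )
            out[side][segment] = LandmarkSet(
                points=np.array(groups[side]), side=side, segment=segment
            )
    return out


def run_stitch(config) -> dict:
    """Run the full stitching pipeline; returns (and writes) the run report.

    ``config`` is a mapping or the path of a YAML file with keys:
    ``inputs`` (paths of the four series directories: upper_ct, upper_pet,
    lower_ct, lower_pet), ``landmarks`` (inline mapping or path) or
    ``auto_bb: true``, optional ``plane_z`` (mm), ``half_life`` (s) override,
    ``bb_detection`` parameter overrides, and ``output_dir``.
    """
    cfg = _load_config(config)
    report: dict = {"config": {k: str(v) if isinstance(v, Path) else v for k, v in cfg.items() if k != "landmarks"}}
    captured: list[str] = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with _stage("load"):
            inputs = cfg["inputs"]
            vols: dict[str, VolumeGrid] = {}
            metas: dict[str, dicom_io.SeriesMeta] = {}
            for name in ("upper_ct", "upper_pet", "lower_ct", "lower_pet"):
                vols[name], metas[name] = dicom_io.read_series(inputs[name])
            if cfg.get("half_life"):
                from dataclasses import replace

                for name in ("upper_pet", "lower_pet"):
                    metas[name] = replace(metas[name], half_life=float(cfg["half_life"]))
            ct_grids = {"upper": vols["upper_ct"], "lower": vols["lower_ct"]}

        with _stage("leg split"):
            partitions = {seg: segmentation.split_legs(ct_grids[seg]) for seg in SEGMENTS}
            partition = partitions["lower"]
            report["leg_boundary_lower"] = partition.boundary.tolist()

        with _stage("landmark localization"):
            if cfg.get("auto_bb"):
                landmarks = _landmarks_auto(
                    ct_grids, partitions, cfg.get("bb_detection", {})
                )
            else:
                landmarks = _landmarks_from_config(cfg["landmarks"], ct_grids)
            report["landmarks_mm"] = {
                side: {seg: lm.points.tolist() for seg, lm in by_seg.items()}
                for side, by_seg in landmarks.items()
            }

        with _stage("transform solve"):
            transforms: dict[str, geometry.StitchTransform] = {}
            report["correspondence"] = {}
            for side in SIDES:
                lm_u, lm_l = landmarks[side]["upper"], landmarks[side]["lower"]
                perm, residual = geometry.match_landmarks(lm_u, lm_l)
                t = geometry.solve_transform(lm_u, lm_l.permuted(perm))
                transforms[side] = t
                report["correspondence"][side] = {
                    "permutation": list(perm),
                    "congruence_residual_mm": residual,
                    "rotation_deg": t.rotation_angle_deg(),
                }
            if cfg.get("plane_z") is not None:
                plane_z = float(cfg["plane_z"])
            else:
                pts = np.vstack([landmarks[s]["upper"].points for s in SIDES])
                plane_z = float(pts.mean(axis=0) @ vols["upper_ct"].normal)
            report["plane_z_mm"] = plane_z

        with _stage("decay correction"):
            meta_lp, ctx = _decay.apply_decay_correction(
                metas["lower_pet"], metas["upper_pet"]
            )
            report["decay"] = {
                "delta_t_s": ctx.delta_t,
                "half_life_s": ctx.half_life,
                "factor": ctx.factor,
            }
            from dataclasses import replace as _replace

            lower_pet = _replace_volume_slope(vols["lower_pet"], meta_lp.rescale_slope)

        with _stage("resample and stitch"):
            stitched: dict[str, VolumeGrid] = {}
            for modality, upper_vol, lower_vol in (
                ("ct", vols["upper_ct"], vols["lower_ct"]),
                ("pet", vols["upper_pet"], lower_pet),
            ):
                out_grid = resample.build_stitched_grid(
                    upper_vol, lower_vol, transforms, plane_z
                )
                res, claimed = resample.resample_segment(
                    lower_vol, partition, transforms, out_grid
                )
                emb = resample.embed_on_grid(upper_vol, out_grid)
                vol = resample.stitch_volumes(emb, res, plane_z)
                below = vol.slice_positions() <= plane_z
                gap = (~claimed) & below[None, None, :]
                vol = segmentation.fill_gap(vol, gap)
                stitched[modality] = vol
                report[f"stitched_{modality}_shape"] = list(vol.shape)
                report[f"stitched_{modality}_origin_mm"] = vol.origin.tolist()

        report["warnings"] = [str(w.message) for w in wrec]
        for w in wrec:
            logger.warning("%s", w.message)

    with _stage("write output"):
        output_dir = Path(cfg["output_dir"])
        entropy = f"petstitch-stitch-{metas['upper_ct'].study_uid}"
        desc = cfg.get("series_description", "Whole-body stitched")
        report["outputs"] = {}
        for modality, template in (("ct", metas["upper_ct"]), ("pet", metas["upper_pet"])):
            out = output_dir / f"stitched_{modality}"
            dicom_io.write_stitched_series(
                stitched[modality],
                template,
                out,
                series_description=f"{desc} {modality.upper()}",
                uid_entropy=entropy,
            )
            report["outputs"][modality] = str(out)
        report_path = Path(cfg.get("report", output_dir / "report.json"))
        report_path.parent.mkdir(parents=True, exist_ok=True)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2)
        report["report_path"] = str(report_path)
    return report


def _replace_volume_slope(vol: VolumeGrid, slope) -> VolumeGrid:
    return VolumeGrid(
        values=vol.values,
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
        modality=vol.modality,
        slope=slope,
        intercept=vol.intercept,
    )


def generate_fixture(config) -> dict:
    """Generate a phantom study on disk from a configuration mapping/file.

    Keys: ``spec`` (PhantomSpec fields, inline mapping or YAML path,
    optional), ``output_dir``, ``seed`` (optional override).
    """
    cfg = _load_config(config)
    spec_cfg = cfg.get("spec")
    if isinstance(spec_cfg, (str, Path)):
        spec = PhantomSpec.from_yaml(spec_cfg)
    elif spec_cfg:
        spec = PhantomSpec.from_dict(spec_cfg)
    else:
        spec = PhantomSpec()
    study = generate_phantom(spec, seed=cfg.get("seed"))
    paths = study.write(cfg["output_dir"])
    return {name: str(p) for name, p in paths.items()}
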