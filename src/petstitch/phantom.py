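"""Synthetic two-segment PET/CT phantom with full ground truth.

The generator emulates a physical two-bottle phantom: two water cylinders
standing in for the legs, filled with a uniform 18F activity concentration
of 3.33 kBq/cc, with three radio-opaque 2 mm BBs taped to each cylinder's
surface inside the axial band imaged by both segments.  Between the two
acquisitions each cylinder undergoes a known rigid motion (the bottles are
re-oriented) and the activity decays over a 30 minute delay.  Both segments
are rendered analytically onto CT-like (0.97 x 0.97 x 3.27 mm) and coarser
PET voxel grids and can be written as standard DICOM series, so the whole
pipeline — BB detection, per-leg transform recovery, resampling, decay
correction, DICOM round trip — is testable against exact ground truth with
no external data.

What it does not emulate: PET projection/reconstruction physics (scatter,
randoms, partial volume, OSEM texture) and CT beam hardening.  PET noise is
modelled as Gaussian with standard deviation proportional to the local true
activity (default 5% coefficient of variation), which keeps air exactly at
zero as in the gap-fill convention.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .dicom_io import SeriesMeta, VolumeGrid, write_series

__all__ = [
    "LegMotion",
    "PhantomSpec",
    "GroundTruth",
    "PhantomStudy",
    "generate_phantom",
    "profile_activity",
]

KBQ_CC_TO_BQ_ML = 1000.0  # 1 kBq/cc = 1000 Bq/mL

_REFERENCE_TIME = _dt.datetime(2012, 5, 10, 10, 0, 0)


@dataclass(frozen=True)
class LegMotion:
    """Rigid motion of one leg between the two acquisitions.

    Rotation of ``angle_deg`` about ``axis`` through ``center`` (patient mm),
    followed by ``translation``.  Maps segment-one anatomy into its
    segment-two appearance.
    """

    angle_deg: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return Rotation.from_rotvec(np.radians(self.angle_deg) * axis).as_matrix()

    def apply(self, pts) -> np.ndarray:
        p = np.asarray(pts, dtype=float)
        r = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (p - c) @ r.T + c + t

    def inverse_apply(self, pts) -> np.ndarray:
        p = np.asarray(pts, dtype=float)
        r = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (p - c - t) @ r + c

    def true_stitch_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """(L, o) of the ground-truth segment-two -> segment-one map X = L.Y + o."""
        r = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return r.T, c - r.T @ (c + t)

    def to_dict(self) -> dict:
        return {
            "angle_deg": float(self.angle_deg),
            "axis": [float(x) for x in self.axis],
            "center": [float(x) for x in self.center],
            "translation": [float(x) for x in self.translation],
        }


@dataclass
class PhantomSpec:
    """Full description of a synthetic two-segment study.

    Defaults mirror the reference phantom protocol: 3.33 kBq/cc of 18F,
    30 min inter-segment delay, CT voxels 0.97 x 0.97 x 3.27 mm, three BBs
    per leg in the overlap band, and a modest rigid re-orientation of each
    leg between the segments.
    """

    leg_radius_mm: float = 45.0
    leg_separation_mm: float = 120.0  # center-to-center
    activity_kbq_cc: float = 3.33
    background_hu: float = -1000.0
    leg_hu: float = 40.0
    bb_hu: float = 8000.0
    bb_radius_mm: float = 1.5
    bb_positions: dict[str, np.ndarray] | None = None  # per side, (3, 3) mm
    motion: dict[str, LegMotion] | None = None
    inter_segment_delay_s: float = 1800.0
    half_life_s: float = 6586.2
    ct_spacing: tuple[float, float, float] = (0.97, 0.97, 3.27)
    ct_shape: tuple[int, int, int] = (256, 256, 120)
    pet_spacing: tuple[float, float, float] = (2.73, 2.73, 3.27)
    pet_shape: tuple[int, int, int] = (128, 128, 120)
    overlap_mm: float = 52.32  # 16 CT slices
    pet_noise_cv: float = 0.05
    ct_noise_hu: float = 0.0
    seed: int = 0
    lower_feet_first: bool = False

    # ---- derived geometry -------------------------------------------------

    @property
    def segment_extent_mm(self) -> float:
        """Axial extent of one segment (slice count times interval)."""
        return self.ct_shape[2] * self.ct_spacing[2]

    @property
    def upper_z0(self) -> float:
        """Axial position of the upper segment's lowest slice center; the
        lower segment's lowest slice center sits at z = 0."""
        return self.segment_extent_mm - self.overlap_mm

    @property
    def overlap_band(self) -> tuple[float, float]:
        return self.upper_z0, self.segment_extent_mm - self.ct_spacing[2]

    def leg_center_x(self, side: str) -> float:
        return -self.leg_separation_mm / 2 if side == "left" else self.leg_separation_mm / 2

    def __post_init__(self) -> None:
        if self.bb_positions is None:
            self.bb_positions = self._default_bbs()
        else:
            self.bb_positions = {
                s: np.asarray(p, dtype=float) for s, p in self.bb_positions.items()
            }
        if self.motion is None:
            self.motion = self._default_motion()
        self.validate()

    def _default_bbs(self) -> dict[str, np.ndarray]:
        lo, hi = self.overlap_band
        zs = lo + (hi - lo) * np.array([0.3, 0.5, 0.7])
        out = {}
        for side, thetas in (("left", (170.0, 80.0, 260.0)), ("right", (10.0, 100.0, 280.0))):
            cx = self.leg_center_x(side)
            th = np.radians(thetas)
            out[side] = np.column_stack(
                [
                    cx + self.leg_radius_mm * np.cos(th),
                    self.leg_radius_mm * np.sin(th),
                    zs,
                ]
            )
        return out

    def _default_motion(self) -> dict[str, LegMotion]:
        z_mid = (self.overlap_band[0] + self.overlap_band[1]) / 2
        return {
            "left": LegMotion(
                angle_deg=4.0,
                axis=(0.0, 0.0, 1.0),
                center=(self.leg_center_x("left"), 0.0, z_mid),
                translation=(3.0, -2.0, 4.0),
            ),
            "right": LegMotion(
                angle_deg=-3.0,
                axis=(0.06, 0.0, 1.0),
                center=(self.leg_center_x("right"), 0.0, z_mid),
                translation=(-2.5, 3.0, 4.0),
            ),
        }

    def validate(self) -> None:
        dz = max(self.ct_spacing[2], self.pet_spacing[2])
        if self.overlap_mm < 2 * dz:
            raise ValueError(
                f"overlap band ({self.overlap_mm} mm) must be at least twice "
                f"the slice spacing ({dz} mm)"
            )
        lo, hi = self.overlap_band
        for side, pts in self.bb_positions.items():
            if pts.shape != (3, 3):
                raise ValueError(f"{side}: need exactly three BB positions")
            if np.any(pts[:, 2] < lo) or np.any(pts[:, 2] > hi):
                raise ValueError(
                    f"{side}: BBs at z={pts[:, 2]} outside the overlap band "
                    f"[{lo:.1f}, {hi:.1f}] mm"
                )
            cx = self.leg_center_x(side)
            r = np.hypot(pts[:, 0] - cx, pts[:, 1])
            if np.any(np.abs(r - self.leg_radius_mm) > 10.0):
                raise ValueError(f"{side}: BBs must sit on the leg surface")
        # motion must keep the legs inside the transaxial field of view
        fov_x = self.ct_shape[0] * self.ct_spacing[0] / 2
        fov_y = self.ct_shape[1] * self.ct_spacing[1] / 2
        for side, m in self.motion.items():
            c = np.array([self.leg_center_x(side), 0.0, 0.0])
            moved = m.apply(c)
            if (
                abs(moved[0]) + self.leg_radius_mm > fov_x
                or abs(moved[1]) + self.leg_radius_mm > fov_y
            ):
                raise ValueError(f"{side}: motion pushes the leg outside the field of view")

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "leg_radius_mm", "leg_separation_mm", "activity_kbq_cc",
                "background_hu", "leg_hu", "bb_hu", "bb_radius_mm",
                "inter_segment_delay_s", "half_life_s", "overlap_mm",
                "pet_noise_cv", "ct_noise_hu", "seed", "lower_feet_first",
            )
        }
        d["ct_spacing"] = list(self.ct_spacing)
        d["ct_shape"] = list(self.ct_shape)
        d["pet_spacing"] = list(self.pet_spacing)
        d["pet_shape"] = list(self.pet_shape)
        d["bb_positions"] = {s: p.tolist() for s, p in self.bb_positions.items()}
        d["motion"] = {s: m.to_dict() for s, m in self.motion.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("ct_spacing", "ct_shape", "pet_spacing", "pet_shape"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("motion") is not None:
            d["motion"] = {s: LegMotion(**m) for s, m in d["motion"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class GroundTruth:
    """Everything a test harness needs to score a stitched result."""

    motions: dict[str, LegMotion]
    bb_upper: dict[str, np.ndarray]  # true BB positions, segment one, mm
    bb_lower: dict[str, np.ndarray]  # true (moved) BB positions, segment two, mm
    activity_bq_ml_upper: float
    activity_bq_ml_lower: float
    reference_time_upper: _dt.datetime
    reference_time_lower: _dt.datetime
    half_life_s: float
    overlap_band: tuple[float, float]

    def true_affine(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        return self.motions[side].true_stitch_affine()

    def to_dict(self) -> dict:
        return {
            "motions": {s: m.to_dict() for s, m in self.motions.items()},
            "bb_upper": {s: p.tolist() for s, p in self.bb_upper.items()},
            "bb_lower": {s: p.tolist() for s, p in self.bb_lower.items()},
            "activity_bq_ml_upper": self.activity_bq_ml_upper,
            "activity_bq_ml_lower": self.activity_bq_ml_lower,
            "reference_time_upper": self.reference_time_upper.isoformat(),
            "reference_time_lower": self.reference_time_lower.isoformat(),
            "half_life_s": self.half_life_s,
            "overlap_band": list(self.overlap_band),
        }


@dataclass
class PhantomStudy:
    """Generated study: four volumes with metadata plus the ground truth."""

    upper_ct: tuple[VolumeGrid, SeriesMeta]
    upper_pet: tuple[VolumeGrid, SeriesMeta]
    lower_ct: tuple[VolumeGrid, SeriesMeta]
    lower_pet: tuple[VolumeGrid, SeriesMeta]
    ground_truth: GroundTruth
    spec: PhantomSpec

    def write(self, directory) -> dict[str, Path]:
        """Write the four DICOM series plus ground truth as YAML."""
        directory = Path(directory)
        paths = {}
        for name in ("upper_ct", "upper_pet", "lower_ct", "lower_pet"):
            vol, meta = getattr(self, name)
            out = directory / name
            write_series(vol, meta, out)
            paths[name] = out
        gt_path = directory / "ground_truth.yaml"
        with open(gt_path, "w") as fh:
            yaml.safe_dump(self.ground_truth.to_dict(), fh, sort_keys=True)
        paths["ground_truth"] = gt_path
        return paths


def _make_grid(shape, spacing, z0: float, feet_first: bool) -> tuple[np.ndarray, np.ndarray]:
    """Origin and orientation of a segment grid centered on the patient axis.

    A feet-first acquisition stores the same patient-space content with the
    row direction reversed and slices running head-to-foot; the orientation
    tags encode this so reading normalizes it away.
    """
    ni, nj, nk = shape
    dx, dy, dz = spacing
    if not feet_first:
        orientation = np.eye(3)
        origin = np.array([-(ni - 1) * dx / 2, -(nj - 1) * dy / 2, z0])
    else:
        orientation = np.diag([-1.0, 1.0, -1.0])
        origin = np.array([(ni - 1) * dx / 2, -(nj - 1) * dy / 2, z0 + (nk - 1) * dz])
    return origin, orientation


def _voxel_centers(grid: VolumeGrid) -> np.ndarray:
    ni, nj, nk = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij")
    return grid.voxel_to_patient(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))


def _inside_legs(pts: np.ndarray, spec: PhantomSpec, motions: dict[str, LegMotion] | None) -> np.ndarray:
    inside = np.zeros(len(pts), dtype=bool)
    for side in ("left", "right"):
        q = pts if motions is None else motions[side].inverse_apply(pts)
        cx = spec.leg_center_x(side)
        inside |= (q[:, 0] - cx) ** 2 + q[:, 1] ** 2 <= spec.leg_radius_mm**2
    return inside


def _paint_bbs(
    values_hu: np.ndarray, grid: VolumeGrid, centers: np.ndarray, spec: PhantomSpec
) -> None:
    """Render BB spheres with sub-voxel partial-volume weighting (in place)."""
    sub = 4  # supersampling factor per axis
    offs = (np.arange(sub) + 0.5) / sub - 0.5
    oi, oj, ok = np.meshgrid(offs, offs, offs, indexing="ij")
    sub_offsets = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3)
    r = spec.bb_radius_mm
    for c in centers:
        c_idx = grid.patient_to_voxel(c)
        half = (r + np.max(grid.spacing)) / grid.spacing
        lo = np.maximum(np.ceil(c_idx - half).astype(int), 0)
        hi = np.minimum(np.floor(c_idx + half).astype(int), np.array(grid.shape) - 1)
        if np.any(lo > hi):
            continue
        ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        sub_idx = idx[:, None, :] + sub_offsets[None, :, :]
        sub_pts = grid.voxel_to_patient(sub_idx.reshape(-1, 3))
        d2 = np.sum((sub_pts - c) ** 2, axis=1).reshape(len(idx), -1)
        frac = np.mean(d2 <= r**2, axis=1)
        sel = frac > 0
        if not sel.any():
            continue
        flat = idx[sel].astype(int)
        base = values_hu[flat[:, 0], flat[:, 1], flat[:, 2]]
        values_hu[flat[:, 0], flat[:, 1], flat[:, 2]] = base + frac[sel] * (
            spec.bb_hu - base
        )


def _render_ct(
    grid_geom: tuple[np.ndarray, np.ndarray],
    shape,
    spacing,
    spec: PhantomSpec,
    motions: dict[str, LegMotion] | None,
    bb_centers: np.ndarray,
    rng: np.random.Generator,
) -> VolumeGrid:
    origin, orientation = grid_geom
    grid = VolumeGrid(
        values=np.zeros(shape, dtype=np.int16),
        spacing=spacing,
        origin=origin,
        orientation=orientation,
        modality="CT",
    )
    pts = _voxel_centers(grid)
    hu = np.where(
        _inside_legs(pts, spec, motions), spec.leg_hu, spec.background_hu
    ).reshape(shape)
    _paint_bbs(hu, grid, bb_centers, spec)
    if spec.ct_noise_hu > 0:
        hu = hu + rng.normal(0.0, spec.ct_noise_hu, size=hu.shape)
    grid.values = np.rint(hu).astype(np.int16)
    return grid


def _render_pet(
    grid_geom: tuple[np.ndarray, np.ndarray],
    shape,
    spacing,
    spec: PhantomSpec,
    motions: dict[str, LegMotion] | None,
    activity_bq_ml: float,
    rng: np.random.Generator,
) -> VolumeGrid:
    origin, orientation = grid_geom
    slope = activity_bq_ml * 1.5 / 30000.0
    grid = VolumeGrid(
        values=np.zeros(shape, dtype=np.int16),
        spacing=spacing,
        origin=origin,
        orientation=orientation,
        modality="PT",
        slope=slope,
    )
    pts = _voxel_centers(grid)
    act = np.where(_inside_legs(pts, spec, motions), activity_bq_ml, 0.0).reshape(shape)
    if spec.pet_noise_cv > 0:
        act = act + rng.normal(0.0, 1.0, size=act.shape) * (spec.pet_noise_cv * act)
    grid.values = np.rint(act / slope).astype(np.int16)
    return grid


def generate_phantom(spec: PhantomSpec | None = None, seed: int | None = None) -> PhantomStudy:
    """Render the two-segment phantom study with ground truth.

    Deterministic given the seed (``seed`` overrides ``spec.seed``); the
    lower segment equals the upper segment's anatomy with the per-leg motion
    applied and the activity decayed by ``2^(-delay/half_life)``.
    """
    spec = spec if spec is not None else PhantomSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    a_upper = spec.activity_kbq_cc * KBQ_CC_TO_BQ_ML
    a_lower = a_upper * 2.0 ** (-spec.inter_segment_delay_s / spec.half_life_s)
    t_upper = _REFERENCE_TIME
    t_lower = t_upper + _dt.timedelta(seconds=spec.inter_segment_delay_s)

    bb_upper = {s: np.asarray(p, float) for s, p in spec.bb_positions.items()}
    bb_lower = {s: spec.motion[s].apply(p) for s, p in bb_upper.items()}
    all_bb_upper = np.vstack([bb_upper["left"], bb_upper["right"]])
    all_bb_lower = np.vstack([bb_lower["left"], bb_lower["right"]])

    upper_geom_ct = _make_grid(spec.ct_shape, spec.ct_spacing, spec.upper_z0, False)
    upper_geom_pet = _make_grid(spec.pet_shape, spec.pet_spacing, spec.upper_z0, False)
    lower_geom_ct = _make_grid(spec.ct_shape, spec.ct_spacing, 0.0, spec.lower_feet_first)
    lower_geom_pet = _make_grid(spec.pet_shape, spec.pet_spacing, 0.0, spec.lower_feet_first)

    upper_ct = _render_ct(upper_geom_ct, spec.ct_shape, spec.ct_spacing, spec, None, all_bb_upper, rng)
    upper_pet = _render_pet(upper_geom_pet, spec.pet_shape, spec.pet_spacing, spec, None, a_upper, rng)
    lower_ct = _render_ct(lower_geom_ct, spec.ct_shape, spec.ct_spacing, spec, spec.motion, all_bb_lower, rng)
    lower_pet = _render_pet(lower_geom_pet, spec.pet_shape, spec.pet_spacing, spec, spec.motion, a_lower, rng)

    from pydicom.uid import generate_uid

    entropy = f"petstitch-phantom-{seed}"
    study_uid = generate_uid(entropy_srcs=[entropy + "/study"])
    frame_uid = generate_uid(entropy_srcs=[entropy + "/frame"])

    def meta_for(name: str, vol: VolumeGrid, t: _dt.datetime) -> SeriesMeta:
        return SeriesMeta(
            modality=vol.modality,
            reference_time=t,
            rescale_slope=vol.slope,
            rescale_intercept=vol.intercept,
            half_life=spec.half_life_s if vol.modality == "PT" else None,
            series_description=f"phantom {name}",
            number_of_slices=vol.shape[2],
            study_uid=study_uid,
            series_uid=generate_uid(entropy_srcs=[f"{entropy}/{name}"]),
            frame_uid=frame_uid,
            uid_entropy=entropy,
        )

    gt = GroundTruth(
        motions=dict(spec.motion),
        bb_upper=bb_upper,
        bb_lower=bb_lower,
        activity_bq_ml_upper=a_upper,
        activity_bq_ml_lower=a_lower,
        reference_time_upper=t_upper,
        reference_time_lower=t_lower,
        half_life_s=spec.half_life_s,
        overlap_band=spec.overlap_band,
    )
    return PhantomStudy(
        upper_ct=(upper_ct, meta_for("upper_ct", upper_ct, t_upper)),
        upper_pet=(upper_pet, meta_for("upper_pet", upper_pet, t_upper)),
        lower_ct=(lower_ct, meta_for("lower_ct", lower_ct, t_lower)),
        lower_pet=(lower_pet, meta_for("lower_pet", lower_pet, t_lower)),
        ground_truth=gt,
        spec=spec,
    )


def profile_activity(
    pet: VolumeGrid,
    roi_pixels: int = 50,
    x_range: tuple[float, float] | None = None,
    slices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axial-slice mean activity over a fixed-size circular-ish ROI.

    On every evaluated slice the activity-weighted in-plane centroid is
    located (restricted to ``x_range`` in patient mm when given, e.g. one
    leg), and the mean physical value over exactly ``roi_pixels`` pixels
    nearest that centroid is reported, matching the profile convention of a
    50-pixel ROI per slice.

    Returns (slice indices, mean activity per slice in physical units).
    """
    phys = pet.physical()
    ni, nj, nk = pet.shape
    if roi_pixels > ni * nj:
        raise ValueError("ROI larger than the slice")
    if slices is None:
        slices = np.arange(nk)
    slices = np.asarray(slices, dtype=int)
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    flat_idx = np.stack([ii, jj], axis=-1).reshape(-1, 2)
    means = np.empty(len(slices))
    for n, k in enumerate(slices):
        idx3 = np.column_stack([flat_idx, np.full(len(flat_idx), k)])
        pts = pet.voxel_to_patient(idx3)
        slab = phys[:, :, k].reshape(-1)
        if x_range is not None:
            sel = (pts[:, 0] >= x_range[0]) & (pts[:, 0] <= x_range[1])
        else:
            sel = np.ones(len(slab), dtype=bool)
        if not sel.any():
            raise ValueError(f"x_range selects no pixels on slice {k}")
        w = np.clip(slab[sel], 0.0, None)
        if w.sum() <= 0:
            means[n] = 0.0
            continue
        cx = np.average(pts[sel, 0], weights=w)
        cy = np.average(pts[sel, 1], weights=w)
        d2 = (pts[sel, 0] - cx) ** 2 + (pts[sel, 1] - cy) ** 2
        nearest = np.argsort(d2)[:roi_pixels]
        means[n] = float(slab[sel][nearest].mean())
    return slices, means
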