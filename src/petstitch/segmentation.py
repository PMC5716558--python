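"""Leg splitting, fiducial (BB) detection and air gap filling on CT.

The lower body segment contains two legs that may have moved independently
between the acquisitions, so it is split into a left and a right part before
per-leg registration.  The split follows the minimum-intensity rule: on each
axial slice the anterior-posterior column sums are computed over the central
half of the left-right extent and the minimizing column (air between the
legs) becomes the boundary, smoothed across slices with a running median.

BBs are 2 mm radio-opaque pellets taped to the skin.  They are detected by
HU thresholding and 26-connected component analysis, keeping components whose
physical volume is small (rejecting metal implants, which are much larger)
and whose centroid lies near the body surface (implants sit deep in the
body).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dicom_io import VolumeGrid

__all__ = [
    "LegPartition",
    "BBCandidate",
    "BBDetectionError",
    "LegSplitWarning",
    "split_legs",
    "detect_bbs",
    "refine_landmark",
    "fill_gap",
]

#: Default HU threshold separating BBs/metal from tissue and bone.
BB_HU_THRESHOLD = 2000.0
#: Default physical volume window for a BB component (mm^3).
BB_VOLUME_RANGE = (1.0, 100.0)
#: Default maximum centroid distance from the body surface (mm).
BB_SURFACE_BAND = 10.0
#: HU threshold delimiting the body from air.
BODY_HU_THRESHOLD = -400.0
#: Margin over air below which a column-sum minimum counts as a true gap.
AIR_MARGIN_HU = 300.0


class BBDetectionError(RuntimeError):
    """Automatic BB detection could not return the expected landmarks."""


class LegSplitWarning(UserWarning):
    """The legs could not be separated by an air gap; midline fallback used."""


@dataclass
class LegPartition:
    """Per-slice sagittal boundary between the two legs plus side masks.

    ``boundary`` holds the boundary voxel column per axial slice of the CT
    grid it was computed on.  ``left_mask``/``right_mask`` are the side
    regions of that grid (columns strictly left/right of the boundary); the
    boundary column itself belongs to neither and is treated as gap.
    """

    boundary: np.ndarray  # (nk,) int, CT voxel column per slice
    left_mask: np.ndarray  # bool, CT grid
    right_mask: np.ndarray
    grid: VolumeGrid  # geometry reference (values not retained by contract)

    def boundary_curve_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary as patient-space (z, x) samples, one per CT slice."""
        nk = len(self.boundary)
        mid_row = (self.grid.shape[1] - 1) / 2.0
        idx = np.column_stack(
            [self.boundary.astype(float), np.full(nk, mid_row), np.arange(nk)]
        )
        pts = self.grid.voxel_to_patient(idx)
        order = np.argsort(pts[:, 2])
        return pts[order, 2], pts[order, 0]

    def boundary_x_at(self, z) -> np.ndarray:
        """Interpolated boundary patient x (mm) at axial position(s) z."""
        zs, xs = self.boundary_curve_mm()
        return np.interp(np.asarray(z, dtype=float), zs, xs)

    def side_of(self, points) -> np.ndarray:
        """'left'/'right' label for patient-space point(s) by boundary side.

        Patient x increases toward the patient's left, but 'left'/'right'
        here name the two image halves consistently with the masks: the
        lower-x half is 'left'.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        bx = self.boundary_x_at(p[:, 2])
        out = np.where(p[:, 0] < bx, "left", "right")
        return out if out.size > 1 else out[0]

    def side_mask_for(self, grid: VolumeGrid, side: str) -> np.ndarray:
        """Boolean mask of ``grid`` voxels on the given side of the boundary.

        Works for any grid sharing the patient frame (e.g. the PET grid of
        the same segment), assuming near-axial slice orientation.
        """
        ni, nj, nk = grid.shape
        ii, jj, kk = np.meshgrid(
            np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        pts = grid.voxel_to_patient(idx)
        bx = self.boundary_x_at(pts[:, 2])
        left = (pts[:, 0] < bx).reshape(ni, nj, nk)
        if side == "left":
            return left
        if side == "right":
            return ~left
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def split_legs(ct: VolumeGrid, air_margin_hu: float = AIR_MARGIN_HU) -> LegPartition:
    """Split a lower-segment CT into left and right legs.

    For each axial slice the stored values are summed along the
    anterior-posterior axis per left-right column; within the central half
    of the extent the minimizing column is taken as the boundary (ties go to
    the column nearest the midline).  Slices whose minimum is not close to
    air (legs touching) fall back to the global midline with a warning.  The
    boundary is smoothed with a 5-slice running median.
    """
    phys = ct.physical()
    ni, nj, nk = ct.shape
    col_sums = phys.sum(axis=1)  # (ni, nk)
    c0, c1 = ni // 4, ni - ni // 4
    mid = (ni - 1) / 2.0
    boundary = np.empty(nk, dtype=float)
    fallback = False
    for k in range(nk):
        sub = col_sums[c0:c1, k]
        m = sub.min()
        if m / nj > -1000.0 + air_margin_hu:
            boundary[k] = mid
            fallback = True
            continue
        cands = np.flatnonzero(sub == m) + c0
        boundary[k] = cands[np.argmin(np.abs(cands - mid))]
    if fallback:
        warnings.warn(
            "no air gap found between the legs on some slices; "
            "falling back to the image midline there",
            LegSplitWarning,
            stacklevel=2,
        )
    boundary = ndimage.median_filter(boundary, size=5, mode="nearest")
    boundary = np.rint(boundary).astype(int)
    cols = np.arange(ni)[:, None, None]
    b = boundary[None, None, :]
    left_mask = np.broadcast_to(cols < b, ct.shape).copy()
    right_mask = np.broadcast_to(cols > b, ct.shape).copy()
    return LegPartition(boundary=boundary, left_mask=left_mask, right_mask=right_mask, grid=ct)


@dataclass(frozen=True)
class BBCandidate:
    """One detected fiducial: weighted centroid, peak HU and volume."""

    center: np.ndarray  # patient mm
    peak_hu: float
    volume_mm3: float


def _body_mask(phys: np.ndarray) -> np.ndarray:
    """Body voxels: HU above the air threshold, largest two components per
    axial slice (the two legs)."""
    raw = phys > BODY_HU_THRESHOLD
    out = np.zeros_like(raw)
    for k in range(raw.shape[2]):
        lab, n = ndimage.label(raw[:, :, k])
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[::-1][:2] + 1
        out[:, :, k] = np.isin(lab, keep)
    return out


def detect_bbs(
    ct: VolumeGrid,
    expected_count: int = 3,
    hu_threshold: float = BB_HU_THRESHOLD,
    volume_range: tuple[float, float] = BB_VOLUME_RANGE,
    surface_band: float = BB_SURFACE_BAND,
) -> list[BBCandidate]:
    """Detect BB fiducials in a CT volume.

    Thresholds at ``hu_threshold``, forms 26-connected components, keeps
    those whose physical volume lies within ``volume_range`` (mm^3) and whose
    centroid lies within ``surface_band`` mm of the body surface, and returns
    their intensity-weighted centroids ranked by peak HU.

    Raises :class:`BBDetectionError` when fewer than ``expected_count``
    survive; warns (and returns everything) when more do.
    """
    phys = ct.physical()
    bw = phys >= hu_threshold
    if not bw.any():
        raise BBDetectionError(
            f"no voxel above {hu_threshold} HU; specify the landmarks manually"
        )
    labels, n = ndimage.label(bw, structure=np.ones((3, 3, 3), dtype=bool))
    voxel_vol = float(np.prod(ct.spacing))

    body = _body_mask(phys)
    interior = ndimage.binary_erosion(body)
    surface = body & ~interior
    if surface.any():
        dist_to_surface = ndimage.distance_transform_edt(
            ~surface, sampling=ct.spacing
        )
    else:  # degenerate input with no body at all
        dist_to_surface = np.full(ct.shape, np.inf)

    candidates: list[BBCandidate] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        vol = comp.sum() * voxel_vol
        if not (volume_range[0] <= vol <= volume_range[1]):
            continue
        w = np.where(comp, phys[sl] - hu_threshold + 1.0, 0.0)
        local = np.array(ndimage.center_of_mass(w))
        idx = local + np.array([s.start for s in sl])
        nearest = np.clip(np.rint(idx).astype(int), 0, np.array(ct.shape) - 1)
        if dist_to_surface[tuple(nearest)] > surface_band:
            continue
        candidates.append(
            BBCandidate(
                center=ct.voxel_to_patient(idx),
                peak_hu=float(phys[sl][comp].max()),
                volume_mm3=float(vol),
            )
        )
    candidates.sort(key=lambda c: -c.peak_hu)
    if len(candidates) < expected_count:
        raise BBDetectionError(
            f"found only {len(candidates)} of {expected_count} expected BBs; "
            "specify the landmarks manually"
        )
    if len(candidates) > expected_count:
        warnings.warn(
            f"found {len(candidates)} BB candidates, expected {expected_count}; "
            "returning all, ranked by peak HU",
            UserWarning,
            stacklevel=2,
        )
    return candidates


def refine_landmark(ct: VolumeGrid, approx, radius: float = 5.0) -> np.ndarray:
    """Snap an approximate landmark to the brightest voxel center nearby.

    Searches voxel centers within ``radius`` mm of ``approx`` and returns the
    center of the maximum-HU voxel, ties broken by proximity to ``approx``.
    """
    approx = np.asarray(approx, dtype=float)
    center_idx = ct.patient_to_voxel(approx)
    half = radius / ct.spacing
    lo = np.maximum(np.ceil(center_idx - half).astype(int), 0)
    hi = np.minimum(np.floor(center_idx + half).astype(int), np.array(ct.shape) - 1)
    if np.any(lo > hi):
        raise ValueError("search sphere contains no in-grid voxels")
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    pts = ct.voxel_to_patient(idx)
    dist = np.linalg.norm(pts - approx, axis=1)
    inside = dist <= radius
    if not inside.any():
        raise ValueError("search sphere contains no in-grid voxels")
    idx, pts, dist = idx[inside], pts[inside], dist[inside]
    vals = ct.physical()[idx[:, 0], idx[:, 1], idx[:, 2]]
    best = np.flatnonzero(vals == vals.max())
    winner = best[np.argmin(dist[best])]
    return pts[winner]


def fill_gap(vol: VolumeGrid, gap_mask: np.ndarray, modality: str | None = None) -> VolumeGrid:
    """Fill gap voxels with air values: -1000 HU for CT, 0 activity for PET.

    Returns a new volume; voxels outside the mask are bit-identical to the
    input.  The fill is expressed in stored units via the volume's rescale
    mapping so the physical value is exact.
    """
    modality = modality or vol.modality
    phys_fill = -1000.0 if modality == "CT" else 0.0
    values = vol.values.copy()
    slopes = vol.slope_per_slice()
    for k in range(vol.shape[2]):
        m = gap_mask[:, :, k]
        if m.any():
            stored = np.rint((phys_fill - vol.intercept) / slopes[k])
            values[m, k] = values.dtype.type(stored)
    out = VolumeGrid(
        values=values,
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
        modality=vol.modality,
        slope=vol.slope,
        intercept=vol.intercept,
    )
    return out
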