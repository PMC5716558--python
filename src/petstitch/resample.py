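"""Output-grid construction, trilinear sampling and per-leg resampling.

The stitched output grid adopts the upper segment's spacing, orientation and
in-plane extent and extends its slice lattice toward the feet until the
rigidly transformed lower segment is covered.  The lower segment is then
populated by inverse mapping: every output voxel center below the stitching
plane is pushed through the inverse of the appropriate leg's transform into
segment-two coordinates and trilinearly interpolated there.  Inverse mapping
expresses the same point correspondence as the forward formulation but
leaves no holes in the output.

Voxels above the stitching plane are copied bit-identically from the upper
segment — the method never alters segment one.  There is no seam blending.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .dicom_io import VolumeGrid
from .geometry import StitchTransform
from .segmentation import LegPartition

__all__ = [
    "InsufficientOverlapError",
    "build_stitched_grid",
    "trilinear_sample",
    "resample_segment",
    "stitch_volumes",
    "embed_on_grid",
    "fill_stored",
]


class InsufficientOverlapError(RuntimeError):
    """The transformed lower segment does not reach the stitching plane."""


def fill_stored(modality: str, slope, intercept: float) -> int:
    """Stored-unit value encoding physical air (-1000 HU for CT, 0 for PET)."""
    phys = -1000.0 if modality == "CT" else 0.0
    s = float(np.min(np.asarray(slope, dtype=float)))
    return int(np.rint((phys - intercept) / s))


def _grid_corners(grid: VolumeGrid) -> np.ndarray:
    n = np.array(grid.shape) - 1
    corners = np.array(
        [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
        dtype=float,
    )
    return grid.voxel_to_patient(corners)


def build_stitched_grid(
    upper: VolumeGrid,
    lower: VolumeGrid,
    transforms: dict[str, StitchTransform],
    plane_z: float,
) -> VolumeGrid:
    """Geometry of the stitched output volume (values initialized to air).

    The grid keeps the upper segment's slice lattice (so upper slices can be
    copied without interpolation) and adds slices below it until every
    transformed corner of the lower grid is reached.  Raises
    :class:`InsufficientOverlapError` when the transformed lower segment
    stays entirely below the stitching plane.
    """
    corners = _grid_corners(lower)
    moved = np.concatenate([t.apply(corners) for t in transforms.values()])
    w = upper.normal
    wpos = moved @ w
    if wpos.max() < plane_z:
        raise InsufficientOverlapError(
            f"transformed lower segment (top at {wpos.max():.1f} mm along the "
            f"slice normal) does not reach the stitching plane at {plane_z:.1f} mm"
        )
    dz = float(upper.spacing[2])
    s0 = float(upper.origin @ w)
    n_extra = max(0, int(np.ceil((s0 - wpos.min()) / dz - 1e-9)))
    shape = (upper.shape[0], upper.shape[1], upper.shape[2] + n_extra)
    fill = fill_stored(upper.modality, upper.slope, upper.intercept)
    return VolumeGrid(
        values=np.full(shape, fill, dtype=np.int32),
        spacing=upper.spacing,
        origin=upper.origin - n_extra * dz * w,
        orientation=upper.orientation,
        modality=upper.modality,
        slope=upper.slope,
        intercept=upper.intercept,
    )


def _sample_volume(values: np.ndarray, idx: np.ndarray, fill_value: float) -> np.ndarray:
    """Trilinear interpolation of ``values`` at continuous voxel indices.

    Points outside the voxel-center hull return ``fill_value`` exactly;
    points on the hull boundary are interpolated normally.
    """
    n = np.array(values.shape, dtype=float) - 1.0
    inside = np.all((idx >= 0.0) & (idx <= n), axis=-1)
    clipped = np.clip(idx, 0.0, n)
    out = ndimage.map_coordinates(
        values.astype(np.float64), clipped.T, order=1, mode="nearest"
    )
    out[~inside] = fill_value
    return out


def trilinear_sample(vol: VolumeGrid, p, fill_value: float = 0.0) -> np.ndarray:
    """Trilinearly sample stored values at patient-space point(s) ``p`` (mm)."""
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    idx = vol.patient_to_voxel(pts)
    out = _sample_volume(vol.values, idx, fill_value)
    return out if out.size > 1 else float(out[0])


def resample_segment(
    lower: VolumeGrid,
    partition: LegPartition,
    transforms: dict[str, StitchTransform],
    out_grid: VolumeGrid,
    fill_value: float | None = None,
) -> tuple[VolumeGrid, np.ndarray]:
    """Resample the lower segment onto the output grid, one leg at a time.

    Each output voxel center is inverse-mapped through a leg's transform into
    segment-two patient space and trilinearly sampled from that leg's side of
    the split; samples landing on the other leg's side or outside the grid
    get ``fill_value``.  Where both legs claim a voxel (only possible in the
    air between them) the left leg wins.

    Returns the resampled volume together with the boolean mask of output
    voxels claimed by either leg (its complement below the stitching plane is
    the inter-leg gap).
    """
    if fill_value is None:
        fill_value = fill_stored(lower.modality, lower.slope, lower.intercept)
    ni, nj, nk = out_grid.shape
    ii, jj, kk = np.meshgrid(np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij")
    out_pts = out_grid.voxel_to_patient(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    )
    result = np.full(ni * nj * nk, float(fill_value))
    claimed = np.zeros(ni * nj * nk, dtype=bool)
    for side in ("left", "right"):
        if side not in transforms:
            continue
        side_mask = partition.side_mask_for(lower, side)
        masked = np.where(side_mask, lower.values, fill_value)
        inv = transforms[side].inverse()
        idx = lower.patient_to_voxel(inv.apply(out_pts))
        vals = _sample_volume(masked, idx, fill_value)
        ok = _sample_volume(side_mask.astype(np.float64), idx, 0.0) >= 0.5
        take = ok & ~claimed
        result[take] = vals[take]
        claimed |= ok
    values = np.rint(result).astype(np.int32).reshape(ni, nj, nk)
    out = VolumeGrid(
        values=values,
        spacing=out_grid.spacing,
        origin=out_grid.origin,
        orientation=out_grid.orientation,
        modality=lower.modality,
        slope=lower.slope,
        intercept=lower.intercept,
    )
    return out, claimed.reshape(ni, nj, nk)


def embed_on_grid(vol: VolumeGrid, out_grid: VolumeGrid) -> VolumeGrid:
    """Place ``vol`` onto the (slice-extended) output grid by bit-copy.

    The output grid shares the volume's in-plane lattice by construction, so
    embedding is pure slice placement; slices outside the volume are air.
    """
    if vol.shape[:2] != out_grid.shape[:2]:
        raise ValueError("in-plane extents differ; cannot embed without resampling")
    dz = float(out_grid.spacing[2])
    w = out_grid.normal
    k_off = int(np.rint(((vol.origin - out_grid.origin) @ w) / dz))
    fill = fill_stored(vol.modality, vol.slope, vol.intercept)
    values = np.full(out_grid.shape, fill, dtype=vol.values.dtype)
    values[:, :, k_off : k_off + vol.shape[2]] = vol.values
    slopes = np.full(out_grid.shape[2], float(np.mean(vol.slope_per_slice())))
    slopes[k_off : k_off + vol.shape[2]] = vol.slope_per_slice()
    return VolumeGrid(
        values=values,
        spacing=out_grid.spacing,
        origin=out_grid.origin,
        orientation=out_grid.orientation,
        modality=vol.modality,
        slope=slopes,
        intercept=vol.intercept,
    )


def stitch_volumes(
    upper: VolumeGrid, resampled_lower: VolumeGrid, plane_z: float
) -> VolumeGrid:
    """Assemble the whole-body volume: hard seam at the stitching plane.

    Slices whose centers lie above ``plane_z`` (along the slice normal) are
    copied from the upper segment, the rest from the resampled lower
    segment.  Both inputs must live on the identical grid.  The per-slice
    rescale slope follows the source of each slice, which is how decay
    correction reaches the former segment-two slices.
    """
    for name in ("spacing", "origin", "orientation"):
        if not np.allclose(getattr(upper, name), getattr(resampled_lower, name), atol=1e-9):
            raise ValueError(f"input grids differ in {name}; resample first")
    if upper.shape != resampled_lower.shape:
        raise ValueError("input grids differ in shape; resample first")
    positions = upper.slice_positions()
    from_upper = positions > plane_z
    values = np.where(from_upper[None, None, :], upper.values, resampled_lower.values)
    slopes = np.where(
        from_upper, upper.slope_per_slice(), resampled_lower.slope_per_slice()
    )
    slope: float | np.ndarray = slopes
    if np.ptp(slopes) == 0:
        slope = float(slopes[0])
    return VolumeGrid(
        values=values,
        spacing=upper.spacing,
        origin=upper.origin,
        orientation=upper.orientation,
        modality=upper.modality,
        slope=slope,
        intercept=upper.intercept,
    )
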