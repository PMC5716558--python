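"""Radioactive decay correction between the two imaging segments.

The lower segment is acquired after the upper one (30 minutes later in the
reference phantom protocol), so its activity concentration has decayed by
2^(-dt/T_half).  The correction references the second PET segment to the
beginning of the first by multiplying its DICOM RescaleSlope by
2^(dt/T_half) — the pixel payload is never rewritten — and by setting its
acquisition time to that of the first segment so downstream software does
not decay-correct a second time.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .dicom_io import SeriesMeta

__all__ = [
    "F18_HALF_LIFE_S",
    "DecayContext",
    "RadionuclideMismatchError",
    "decay_factor",
    "apply_decay_correction",
]

#: Default fluorine-18 half-life in seconds (109.77 min), used when a PET
#: series carries no radiopharmaceutical information.
F18_HALF_LIFE_S = 6586.2


class RadionuclideMismatchError(ValueError):
    """The two PET segments report incompatible half-lives."""


def decay_factor(delta_t: float, half_life: float) -> float:
    """Multiplier 2^(delta_t/half_life) that references activity measured
    ``delta_t`` seconds late back to the reference time.

    ``delta_t`` may be negative (segments scanned out of order), giving a
    factor below one.
    """
    if half_life <= 0:
        raise ValueError(f"half-life must be positive, got {half_life}")
    return float(2.0 ** (delta_t / half_life))


class DecayContext:
    """Resolved decay correction between two series reference times."""

    def __init__(self, delta_t: float, half_life: float):
        self.delta_t = float(delta_t)
        self.half_life = float(half_life)
        self.factor = decay_factor(delta_t, half_life)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DecayContext(delta_t={self.delta_t:.1f}s, "
            f"half_life={self.half_life:.1f}s, factor={self.factor:.5f})"
        )


def apply_decay_correction(
    meta2: SeriesMeta, meta1: SeriesMeta
) -> tuple[SeriesMeta, DecayContext]:
    """Decay-correct the second PET segment to the first segment's time.

    Returns the updated segment-two metadata (RescaleSlope multiplied by the
    decay factor, reference time replaced by segment one's) together with the
    :class:`DecayContext` used, so the run report can record the factor.
    """
    for meta in (meta1, meta2):
        if meta.modality != "PT":
            raise ValueError(f"decay correction applies to PET series, got {meta.modality}")
    hl1 = meta1.half_life
    hl2 = meta2.half_life
    if hl1 is not None and hl2 is not None and abs(hl1 - hl2) > 1.0:
        raise RadionuclideMismatchError(
            f"half-lives differ between segments ({hl1} s vs {hl2} s); "
            "the two series must use the same radionuclide"
        )
    half_life = hl1 if hl1 is not None else hl2
    if half_life is None:
        warnings.warn(
            "no radiopharmaceutical half-life in either series; assuming "
            f"18F ({F18_HALF_LIFE_S} s)",
            UserWarning,
            stacklevel=2,
        )
        half_life = F18_HALF_LIFE_S
    delta_t = (meta2.reference_time - meta1.reference_time).total_seconds()
    if delta_t < 0:
        warnings.warn(
            f"segment two was acquired {-delta_t:.0f} s before segment one; "
            "applying a decay factor below one",
            UserWarning,
            stacklevel=2,
        )
    ctx = DecayContext(delta_t, half_life)
    new_slope = np.asarray(meta2.rescale_slope, dtype=float) * ctx.factor
    if new_slope.ndim == 0:
        new_slope = float(new_slope)
    updated = replace(
        meta2, rescale_slope=new_slope, reference_time=meta1.reference_time
    )
    return updated, ctx
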