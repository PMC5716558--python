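"""Shared fixtures: a desk-scale phantom study and one stitched run.

The small phantom keeps the default study conditions (uniform 3.33 kBq/cc,
30 min delay, 5% CV PET noise, three BBs per leg, rigid per-leg motion) on a
coarser grid so end-to-end fixtures build in seconds; the BB radius is
scaled with the voxel size so the fiducials stay detectable.
"""

from __future__ import annotations

import numpy as np
import pytest

from petstitch import PhantomSpec, generate_phantom, run_stitch


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        leg_radius_mm=22.0,
        leg_separation_mm=60.0,
        ct_spacing=(2.0, 2.0, 3.0),
        ct_shape=(96, 96, 36),
        pet_spacing=(4.0, 4.0, 3.0),
        pet_shape=(48, 48, 36),
        overlap_mm=24.0,
        bb_radius_mm=2.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_run(small_study, tmp_path_factory):
    """Write the small study to disk and stitch it with automatic BB detection."""
    base = tmp_path_factory.mktemp("small_run")
    indir = base / "inputs"
    paths = small_study.write(indir)
    outdir = base / "stitched"
    report = run_stitch(
        {
            "inputs": {
                k: str(paths[k])
                for k in ("upper_ct", "upper_pet", "lower_ct", "lower_pet")
            },
            "auto_bb": True,
            "output_dir": str(outdir),
        }
    )
    return {"study": small_study, "report": report, "outdir": outdir, "indir": indir}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
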