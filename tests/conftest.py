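"""Shared fixtures: small and full-scale synthetic head phantoms.

The small sphere phantom (1 mm isotropic, radius 45 mm) keeps unit and
pipeline tests fast; the full-scale sphere phantom (radius 60 mm, anisotropic
0.5 x 0.5 x 0.625 mm spacing) exercises the pipeline at realistic CT
resolution and is shared, together with its artifact-laden sibling, by the
end-to-end accuracy tests.  All phantoms place the head clear of the default
bottom-band equipment region in every orientation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ct2skin import PhantomSpec, ArtifactSpec, build_phantom
from ct2skin.pipeline import extract_plane_clouds, fuse_clouds


# --- small isotropic sphere phantom (fast) ---------------------------------

SMALL_CENTER = (59.5, 55.0, 62.0)
SMALL_RADIUS = 45.0


@pytest.fixture(scope="session")
def small_sphere_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(120, 120, 112),
        spacing_mm=(1.0, 1.0, 1.0),
        center_mm=SMALL_CENTER,
        skin_semiaxes_mm=(SMALL_RADIUS,) * 3,
        skull_semiaxes_mm=(40.0,) * 3,
        brain_semiaxes_mm=(35.0,) * 3,
    )


@pytest.fixture(scope="session")
def small_sphere_volume(small_sphere_spec):
    return build_phantom(small_sphere_spec)


@pytest.fixture(scope="session")
def small_sphere_raw(small_sphere_volume):
    """Raw (un-downsampled) uniplanar clouds plus QC log."""
    return extract_plane_clouds(small_sphere_volume)


@pytest.fixture(scope="session")
def small_sphere_result(small_sphere_raw):
    raw, qc = small_sphere_raw
    result = fuse_clouds(raw, voxel_mm=1.0)
    return result, qc


# --- full-scale sphere phantom (radius 60 mm, CT-like spacing) -------------

BIG_CENTER = (68.0, 64.0, 78.0)
BIG_RADIUS = 60.0
BIG_GRID = (272, 288, 224)
BIG_SPACING = (0.5, 0.5, 0.625)


@pytest.fixture(scope="session")
def big_sphere_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=BIG_GRID,
        spacing_mm=BIG_SPACING,
        center_mm=BIG_CENTER,
        skin_semiaxes_mm=(BIG_RADIUS,) * 3,
        skull_semiaxes_mm=(54.0,) * 3,
        brain_semiaxes_mm=(48.0,) * 3,
    )


@pytest.fixture(scope="session")
def big_sphere_raw(big_sphere_spec):
    volume = build_phantom(big_sphere_spec)
    return extract_plane_clouds(volume)


@pytest.fixture(scope="session")
def big_sphere_result_1mm(big_sphere_raw):
    raw, _ = big_sphere_raw
    return fuse_clouds(raw, voxel_mm=1.0)


# --- artifact-laden sibling of the full-scale phantom ----------------------

FIDUCIAL_DIRECTIONS = (
    (1.0, 0.0, 0.0),
    (0.0, -1.0, 0.0),
    (0.6, 0.0, 0.8),
)
SLAB_CENTER = (105.0, 125.4, 78.0)
SLAB_HALF = (25.0, 0.9, 50.0)
CAVITY_CENTER = (68.0, 8.0, 78.0)
CAVITY_SEMIAXES = (12.0, 14.0, 12.0)
FIDUCIAL_RADIUS = 4.0


def fiducial_centers(center=BIG_CENTER, radius=BIG_RADIUS):
    c = np.asarray(center)
    out = []
    for d in FIDUCIAL_DIRECTIONS:
        d = np.asarray(d) / np.linalg.norm(d)
        out.append(c + radius * d)
    return out


@pytest.fixture(scope="session")
def big_artifact_spec(big_sphere_spec) -> PhantomSpec:
    artifacts = [
        ArtifactSpec("table_slab", center_mm=SLAB_CENTER, size_mm=SLAB_HALF, hu_value=40.0)
    ]
    for fc in fiducial_centers():
        artifacts.append(
            ArtifactSpec(
                "fiducial_sphere",
                center_mm=tuple(fc),
                size_mm=(FIDUCIAL_RADIUS,) * 3,
                hu_value=800.0,
            )
        )
    artifacts.append(
        ArtifactSpec(
            "intracranial_cavity",
            center_mm=CAVITY_CENTER,
            size_mm=CAVITY_SEMIAXES,
            hu_value=-1000.0,
        )
    )
    return PhantomSpec(
        grid_shape=big_sphere_spec.grid_shape,
        spacing_mm=big_sphere_spec.spacing_mm,
        center_mm=big_sphere_spec.center_mm,
        skin_semiaxes_mm=big_sphere_spec.skin_semiaxes_mm,
        skull_semiaxes_mm=big_sphere_spec.skull_semiaxes_mm,
        brain_semiaxes_mm=big_sphere_spec.brain_semiaxes_mm,
        artifacts=tuple(artifacts),
    )


@pytest.fixture(scope="session")
def big_artifact_result_1mm(big_artifact_spec):
    volume = build_phantom(big_artifact_spec)
    raw, qc = extract_plane_clouds(volume)
    return fuse_clouds(raw, voxel_mm=1.0), qc
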