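"""Synthetic head CT phantoms with analytically known skin surfaces.

A phantom is a layered ellipsoidal "head" voxelized onto an anisotropic grid:
an outer skin ellipsoid filled with soft-tissue HU, a skull shell above the
soft-tissue band, and a brain ellipsoid back inside the band, all embedded in
air.  The layer HU values straddle the -200..+220 HU soft-tissue threshold, so
binarization sees exactly the ring structure a real head produces.  Optional
artifacts emulate the nuisances the reconstruction pipeline must reject:

* ``table_slab``          — a scanner-table/headrest box below the head with
  soft-tissue-range HU (external equipment noise);
* ``fiducial_sphere``     — a high-HU marker sitting on the scalp;
* ``intracranial_cavity`` — an out-of-band ellipsoid that can break the skin
  ring's closure (internal anatomical noise);
* ``nose``                — a soft-tissue ellipsoid protruding from the skin
  surface, exercising the filters on non-convex anatomy.

Because the outer surface is analytic, the per-point distance from any
reconstructed cloud to ground truth is computable to machine precision, which
replaces the mesh-based ground-truth models used with real scans.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .cloud import PointCloud
from .volume import VoxelVolume

__all__ = [
    "ArtifactSpec",
    "PhantomSpec",
    "build_phantom",
    "write_dicom_series",
    "surface_distance",
    "nearest_on_ellipsoid",
    "sample_surface",
    "save_spec",
    "load_spec",
]

_ARTIFACT_KINDS = ("table_slab", "fiducial_sphere", "intracranial_cavity", "nose")


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact: kind, world placement and HU.

    ``size_mm`` is interpreted per kind: half-extents of the box for
    ``table_slab``; ``(radius, radius, radius)`` for ``fiducial_sphere``;
    ellipsoid semi-axes for ``intracranial_cavity`` and ``nose``.
    """

    kind: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    hu_value: float

    def __post_init__(self) -> None:
        if self.kind not in _ARTIFACT_KINDS:
            raise PhantomSpecError(
                f"unknown artifact kind {self.kind!r}; expected one of {_ARTIFACT_KINDS}"
            )
        if any(s <= 0 for s in self.size_mm):
            raise PhantomSpecError(f"artifact size components must be positive: {self.size_mm}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic head volume.

    ``center_mm`` places the layered ellipsoids; when omitted the head sits at
    the grid centre.  HU defaults: air -1000, skin 40, skull 700, brain 30 —
    air and skull fall outside the -200..+220 band, skin and brain inside it.
    """

    grid_shape: tuple[int, int, int]  # (nx, ny, nz)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    skin_semiaxes_mm: tuple[float, float, float] = (70.0, 90.0, 80.0)
    skull_semiaxes_mm: tuple[float, float, float] = (62.0, 82.0, 72.0)
    brain_semiaxes_mm: tuple[float, float, float] = (56.0, 76.0, 66.0)
    hu_air: float = -1000.0
    hu_skin: float = 40.0
    hu_skull: float = 700.0
    hu_brain: float = 30.0
    artifacts: tuple[ArtifactSpec, ...] = ()
    center_mm: Optional[tuple[float, float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise PhantomSpecError(f"grid_shape components must be >= 1: {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError(f"spacing components must be strictly positive: {self.spacing_mm}")
        b, k, s = self.brain_semiaxes_mm, self.skull_semiaxes_mm, self.skin_semiaxes_mm
        if not all(bi < ki < si for bi, ki, si in zip(b, k, s)):
            raise PhantomSpecError(
                "layer semi-axes must satisfy brain < skull < skin componentwise: "
                f"brain={b}, skull={k}, skin={s}"
            )
        if not self.hu_air < -200:
            raise PhantomSpecError(f"hu_air must be < -200, got {self.hu_air}")
        for name, v in (("hu_skin", self.hu_skin), ("hu_brain", self.hu_brain)):
            if not (-200 <= v <= 220):
                raise PhantomSpecError(f"{name} must lie in [-200, 220], got {v}")
        if not self.hu_skull > 220:
            raise PhantomSpecError(f"hu_skull must be > 220, got {self.hu_skull}")
        object.__setattr__(self, "artifacts", tuple(self.artifacts))
        self._validate_artifacts()

    @property
    def head_center_mm(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        return np.asarray(self.origin_mm) + (shape - 1) / 2.0 * np.asarray(self.spacing_mm)

    def _validate_artifacts(self) -> None:
        center = self.head_center_mm
        a_skin = np.asarray(self.skin_semiaxes_mm)
        for art in self.artifacts:
            c = np.asarray(art.center_mm, dtype=float)
            if art.kind == "table_slab":
                # axial image rows traverse +y: "below" the head = larger y
                slab_top = c[1] - art.size_mm[1]
                head_bottom = center[1] + a_skin[1]
                if slab_top <= head_bottom:
                    raise PhantomSpecError(
                        "table_slab must lie strictly below the skin ellipsoid in the "
                        f"axial view (slab starts at y={slab_top:.3f} mm, head ends at "
                        f"y={head_bottom:.3f} mm)"
                    )
            elif art.kind == "fiducial_sphere":
                nearest = nearest_on_ellipsoid(c[None, :], a_skin, center)
                d = float(np.linalg.norm(c - nearest[0]))
                if d > max(self.spacing_mm):
                    raise PhantomSpecError(
                        "fiducial_sphere centre must lie on the skin surface within one "
                        f"voxel (distance {d:.3f} mm, voxel {max(self.spacing_mm)} mm)"
                    )


def _ellipsoid_term(coords: np.ndarray, center: float, semiaxis: float) -> np.ndarray:
    return ((coords - center) / semiaxis) ** 2


def build_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Voxelize a :class:`PhantomSpec` into a :class:`VoxelVolume`.

    Membership is decided at the voxel centre: each voxel takes the HU of the
    innermost layer whose ellipsoid contains its centre, then artifacts (in
    list order) overwrite any voxel they contain.  Deterministic for a fixed
    spec.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    ox, oy, oz = spec.origin_mm
    x = (ox + sx * np.arange(nx)).astype(np.float32)
    y = (oy + sy * np.arange(ny)).astype(np.float32)
    z = (oz + sz * np.arange(nz)).astype(np.float32)
    cx, cy, cz = spec.head_center_mm

    def inside(semiaxes: Sequence[float], center: Sequence[float]) -> np.ndarray:
        ax_, ay_, az_ = semiaxes
        ccx, ccy, ccz = center
        q = (
            _ellipsoid_term(z, ccz, az_)[:, None, None]
            + _ellipsoid_term(y, ccy, ay_)[None, :, None]
            + _ellipsoid_term(x, ccx, ax_)[None, None, :]
        )
        return q <= 1.0

    hu = np.full((nz, ny, nx), spec.hu_air, dtype=np.float32)
    hu[inside(spec.skin_semiaxes_mm, (cx, cy, cz))] = spec.hu_skin
    hu[inside(spec.skull_semiaxes_mm, (cx, cy, cz))] = spec.hu_skull
    hu[inside(spec.brain_semiaxes_mm, (cx, cy, cz))] = spec.hu_brain

    for art in spec.artifacts:
        acx, acy, acz = art.center_mm
        if art.kind == "table_slab":
            ex, ey, ez = art.size_mm
            mask = (
                (np.abs(z - acz) <= ez)[:, None, None]
                & (np.abs(y - acy) <= ey)[None, :, None]
                & (np.abs(x - acx) <= ex)[None, None, :]
            )
        elif art.kind == "fiducial_sphere":
            r = art.size_mm[0]
            q = (
                ((z - acz) ** 2)[:, None, None]
                + ((y - acy) ** 2)[None, :, None]
                + ((x - acx) ** 2)[None, None, :]
            )
            mask = q <= r * r
        else:  # intracranial_cavity, nose: ellipsoids
            mask = inside(art.size_mm, art.center_mm)
        hu[mask] = art.hu_value

    return VoxelVolume(hu=hu, spacing_mm=spec.spacing_mm, origin_mm=spec.origin_mm)


# ---------------------------------------------------------------------------
# DICOM output
# ---------------------------------------------------------------------------


def write_dicom_series(volume: VoxelVolume, directory: str | os.PathLike) -> list[Path]:
    """Write a volume as a single-frame axial CT DICOM series, one file per
    slice, with geometry and rescale tags set so that a conforming reader
    recovers the HU grid exactly (HU values are stored as signed 16-bit
    integers with slope 1 / intercept 0; non-integer HU are rounded).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = volume.shape
    sx, sy, sz = volume.spacing_mm
    ox, oy, oz = volume.origin_mm
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()

    paths: list[Path] = []
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.PatientName = "Phantom^Synthetic"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1

        ds.Rows = ny
        ds.Columns = nx
        ds.PixelSpacing = [f"{sy:.10g}", f"{sx:.10g}"]
        ds.SliceThickness = f"{sz:.10g}"
        ds.ImagePositionPatient = [f"{ox:.10g}", f"{oy:.10g}", f"{oz + k * sz:.10g}"]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = (
            np.round(volume.hu[k]).astype("<i2").tobytes()
        )

        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def save_spec(spec: PhantomSpec, path: str | os.PathLike) -> None:
    """Write a sidecar YAML file recording the analytic surface parameters."""
    import yaml

    payload = asdict(spec)
    payload["artifacts"] = [asdict(a) for a in spec.artifacts]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, default_flow_style=None, sort_keys=False)


def load_spec(path: str | os.PathLike) -> PhantomSpec:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    artifacts = tuple(
        ArtifactSpec(
            kind=a["kind"],
            center_mm=tuple(a["center_mm"]),
            size_mm=tuple(a["size_mm"]),
            hu_value=a["hu_value"],
        )
        for a in payload.pop("artifacts", [])
    )
    tuple_keys = (
        "grid_shape",
        "spacing_mm",
        "origin_mm",
        "skin_semiaxes_mm",
        "skull_semiaxes_mm",
        "brain_semiaxes_mm",
    )
    for key in tuple_keys:
        payload[key] = tuple(payload[key])
    if payload.get("center_mm") is not None:
        payload["center_mm"] = tuple(payload["center_mm"])
    return PhantomSpec(artifacts=artifacts, **payload)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


def nearest_on_ellipsoid(
    points: np.ndarray,
    semiaxes: Sequence[float],
    center: Sequence[float] = (0.0, 0.0, 0.0),
    tol_mm: float = 1e-9,
    max_iter: int = 200,
) -> np.ndarray:
    """Nearest point on a triaxial ellipsoid surface for each query point.

    No closed form exists, so the Lagrange condition ``x_i = a_i^2 p_i /
    (a_i^2 + t)`` is solved for its largest root by Newton iteration on the
    convex decreasing function ``f(t) = sum((a_i p_i / (a_i^2 + t))^2) - 1``,
    with clamping above the leftmost pole.  Accurate to ``tol_mm`` for points
    outside the surface and for interior points near it; for deeply interior
    points on a symmetry axis (inside the evolute) the on-axis critical point
    is returned.  A query at the exact centre maps to the minor-axis vertex.
    """
    a = np.asarray(semiaxes, dtype=float)
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, dtype=float)
    q = np.abs(p)
    aq = a * q
    a2 = a * a

    degenerate = np.all(aq < 1e-14, axis=1)  # at the centre
    safe_aq = np.where(degenerate[:, None], 1.0, aq)

    # leftmost pole: only components with q_i > 0 contribute
    pole = np.where(q > 0, a2, np.inf).min(axis=1)
    t = np.sqrt(3.0) * safe_aq.max(axis=1)  # f(t0) <= 0
    lower = -pole + 1e-12 * a2.max()

    t = np.where(degenerate, 0.0, t)
    for _ in range(max_iter):
        denom = a2[None, :] + t[:, None]
        ratio2 = (safe_aq / denom) ** 2
        f = ratio2.sum(axis=1) - 1.0
        fp = -2.0 * (ratio2 / denom).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(degenerate | (fp == 0.0), 0.0, f / fp)
        t_new = np.maximum(t - step, lower)
        if np.all(np.abs(t_new - t) < tol_mm * 1e-3 + 1e-15):
            t = t_new
            break
        t = t_new

    denom = a2[None, :] + t[:, None]
    x = a2[None, :] * p / denom
    # centre query: nearest surface point is the minor-axis vertex
    if degenerate.any():
        vertex = np.zeros(3)
        j = int(np.argmin(a))
        vertex[j] = a[j]
        x[degenerate] = vertex
    return x + np.asarray(center, dtype=float)


def surface_distance(points: PointCloud, spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Per-point distance (mm) to the phantom's outer skin ellipsoid, and the
    RMS over all points.

    Valid where no artifact alters the outer surface at the queried points
    (fiducials and the nose protrude through it; callers evaluating accuracy
    should restrict to regions away from such artifacts).
    """
    if len(points) == 0:
        raise ValueError("cannot evaluate surface distance of an empty cloud")
    nearest = nearest_on_ellipsoid(
        points.points, spec.skin_semiaxes_mm, spec.head_center_mm
    )
    d = np.linalg.norm(points.points - nearest, axis=1)
    return d, float(np.sqrt(np.mean(d**2)))


def sample_surface(spec: PhantomSpec, n_points: int = 200_000) -> PointCloud:
    """Deterministic quasi-uniform sampling of the outer skin ellipsoid.

    A Fibonacci spiral on the unit sphere is scaled by the semi-axes (exactly
    area-uniform for spherical phantoms, mildly non-uniform for triaxial
    ones) — a point-sampled stand-in for a mesh ground-truth model.
    """
    i = np.arange(n_points, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    zc = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - zc * zc))
    unit = np.column_stack([r * np.cos(theta), r * np.sin(theta), zc])
    pts = unit * np.asarray(spec.skin_semiaxes_mm) + spec.head_center_mm
    return PointCloud(points=pts, source_plane="ground_truth")
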