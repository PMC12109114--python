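"""End-to-end triplanar skin-surface reconstruction.

Stages: reslice the HU volume into the three orientations; binarize each
slice; run the contour validity chain; project every accepted contour into
world millimetres.  The axial cloud's bounding box then clips the sagittal and
coronal clouds, each uniplanar cloud is voxel-downsampled, the three are fused
(union + second downsampling), and outliers are removed.

The expensive part — slice validation and projection — is independent of the
downsampling voxel size, so :func:`extract_plane_clouds` is exposed separately
from :func:`fuse_clouds`; running the pipeline at several voxel sizes reuses
one extraction pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .binarize import DEFAULT_HU_RANGE, HURange, binarize_slice
from .cloud import (
    OutlierParams,
    PointCloud,
    axial_bounding_box,
    clip_to_box,
    contour_to_world,
    merge_triplanar,
    remove_outliers,
    voxel_downsample,
)
from .contours import FilterConfig, validate_slice
from .volume import VoxelVolume, reslice

import numpy as np

__all__ = ["QCRecord", "ReconstructionResult", "extract_plane_clouds", "fuse_clouds", "reconstruct"]

PLANES = ("axial", "sagittal", "coronal")


@dataclass(frozen=True)
class QCRecord:
    """Per-slice quality-control entry."""

    orientation: str
    index: int
    accepted: bool
    reason: str


@dataclass(frozen=True)
class ReconstructionResult:
    """Final and intermediate clouds plus the per-slice QC log."""

    merged: PointCloud
    axial: PointCloud
    sagittal: PointCloud
    coronal: PointCloud
    qc: tuple[QCRecord, ...]

    def qc_summary(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.qc:
            out[rec.reason] = out.get(rec.reason, 0) + 1
        return out


def extract_plane_clouds(
    volume: VoxelVolume,
    hu_range: HURange = DEFAULT_HU_RANGE,
    filter_cfg: FilterConfig = FilterConfig(),
    planes: tuple[str, ...] = PLANES,
) -> tuple[dict[str, PointCloud], list[QCRecord]]:
    """Validate every slice of each requested plane and project accepted
    contours to world coordinates (raw, un-downsampled uniplanar clouds).

    The previous-accepted-contour area used by the four-direction trigger is
    carried independently within each orientation and reset between them.
    """
    clouds: dict[str, PointCloud] = {}
    qc: list[QCRecord] = []
    for plane in planes:
        slices = reslice(volume, plane)
        pts = []
        prev_area: Optional[float] = None
        for sl in slices:
            mask = binarize_slice(sl, hu_range)
            verdict = validate_slice(mask, prev_area_px=prev_area, cfg=filter_cfg)
            qc.append(QCRecord(plane, sl.index, verdict.accepted, verdict.reason))
            if verdict.accepted:
                pts.append(contour_to_world(verdict.contour, sl).points)
                prev_area = verdict.contour.area_px
        merged = np.vstack(pts) if pts else np.empty((0, 3))
        clouds[plane] = PointCloud(points=merged, source_plane=plane)
    return clouds, qc


def fuse_clouds(
    raw: dict[str, PointCloud],
    voxel_mm: float = 1.0,
    outlier_params: OutlierParams = OutlierParams(),
) -> ReconstructionResult:
    """Clip, downsample, merge and de-noise raw uniplanar clouds.

    The axial bounding box is computed from the *downsampled* axial cloud and
    applied to the raw sagittal/coronal clouds before their own downsampling;
    fusion is a set union followed by a second downsampling pass at the same
    voxel size, then the two-stage outlier removal.
    """
    if len(raw.get("axial", PointCloud(points=np.empty((0, 3))))) == 0:
        raise ValueError("axial cloud is empty; cannot establish the bounding box")
    axial = voxel_downsample(raw["axial"], voxel_mm)
    box = axial_bounding_box(axial)
    sagittal = voxel_downsample(
        clip_to_box(raw.get("sagittal", PointCloud(points=np.empty((0, 3)), source_plane="sagittal")), box),
        voxel_mm,
    )
    coronal = voxel_downsample(
        clip_to_box(raw.get("coronal", PointCloud(points=np.empty((0, 3)), source_plane="coronal")), box),
        voxel_mm,
    )
    merged = merge_triplanar(axial, sagittal, coronal, voxel_mm)
    merged = remove_outliers(merged, outlier_params)
    return ReconstructionResult(
        merged=merged, axial=axial, sagittal=sagittal, coronal=coronal, qc=()
    )


def reconstruct(
    volume: VoxelVolume,
    voxel_mm: float = 1.0,
    hu_range: HURange = DEFAULT_HU_RANGE,
    filter_cfg: FilterConfig = FilterConfig(),
    outlier_params: OutlierParams = OutlierParams(),
    planes: tuple[str, ...] = PLANES,
) -> ReconstructionResult:
    """Full pipeline: HU volume in, triplanar skin point cloud out."""
    raw, qc = extract_plane_clouds(volume, hu_range, filter_cfg, planes)
    result = fuse_clouds(raw, voxel_mm, outlier_params)
    return ReconstructionResult(
        merged=result.merged,
        axial=result.axial,
        sagittal=result.sagittal,
        coronal=result.coronal,
        qc=tuple(qc),
    )
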