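"""Contour extraction and the five-filter slice validity chain.

A binarized head slice normally contains one large, nearly convex outer skin
contour.  Medical equipment (scanner table, headrests, wound dressings) and
intracranial structures fall inside the same soft-tissue HU band and create
spurious contours or corrupt the skin ring.  Rather than repairing masks with
morphology, whole slices are *rejected* when their largest contour fails any
of a chain of validity filters — three orthogonal slicing planes provide
enough redundancy that discarding a suspect slice is cheaper than risking
false surface points.

The chain, in fixed order:

1. centroid gate        — equipment contours sit near the image border;
2. first-row pixel connection — re-closes a skin ring broken by intracranial
   noise, then the synthetic row is stripped from the final contour;
3. solidity filter      — large contours must be nearly convex
   (area / convex-hull area >= 0.88, tested only above 40 000 px);
4. four-direction scan  — rays from the contour centroid must not hit
   foreground outside the largest contour (run when the area is consistent
   with the previous accepted slice);
5. row-crossing filter  — scanned rows with many well-separated boundary
   pixels betray comb-like noise (ears, nose, dressings);
6. equipment-region check — any foreground inside configured image regions
   (by default a bottom band where the table sits) rejects the slice.

Every rejection carries a machine-readable reason so a QC report can say why
each slice was dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure
from skimage.draw import polygon2mask

from .binarize import BACKGROUND, FOREGROUND, BinaryMask

__all__ = [
    "Contour",
    "SliceVerdict",
    "FilterConfig",
    "RejectReason",
    "extract_contours",
    "centroid_gate",
    "connect_first_row",
    "strip_connection_row",
    "solidity_check",
    "four_direction_check",
    "row_crossing_check",
    "equipment_region_check",
    "validate_slice",
]


class RejectReason:
    OK = "ok"
    CENTROID = "centroid_out_of_range"
    SOLIDITY = "low_solidity"
    FOUR_DIRECTION = "four_direction_fail"
    ROW_CROSSING = "row_crossing_fail"
    EQUIPMENT = "equipment_region_hit"
    NO_CONTOUR = "no_contour"


@dataclass(frozen=True)
class Contour:
    """A closed polygon in (row, col) pixel coordinates with cached geometry.

    Points come from sub-pixel boundary tracing (the 0.5-level between
    foreground and background pixel centres), ordered along the boundary.
    """

    points: np.ndarray  # (N, 2) float, (row, col)
    area_px: float
    centroid_px: tuple[float, float]

    @classmethod
    def from_points(cls, points: np.ndarray) -> "Contour":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("a contour needs at least 3 (row, col) points")
        poly = Polygon(pts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        c = poly.centroid
        return cls(points=pts, area_px=float(poly.area), centroid_px=(float(c.x), float(c.y)))

    def polygon(self) -> Polygon:
        poly = Polygon(self.points)
        return poly if poly.is_valid else poly.buffer(0)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SliceVerdict:
    """Accept/reject decision for one slice."""

    accepted: bool
    reason: str
    contour: Optional[Contour] = None
    orientation: str = ""
    index: int = -1

    def __post_init__(self) -> None:
        if self.accepted != (self.reason == RejectReason.OK):
            raise ValueError("accepted must hold exactly when reason == 'ok'")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of the validity chain.

    ``centroid_valid_box`` and ``equipment_regions`` are fractional image
    rectangles ``(row_min, row_max, col_min, col_max)`` in [0, 1] so one
    configuration applies to every orientation regardless of image size.
    """

    centroid_valid_box: tuple[float, float, float, float] = (0.0, 0.90, 0.10, 0.90)
    solidity_threshold: float = 0.88
    solidity_min_area_px: float = 40_000.0
    area_delta_trigger: float = 0.15
    row_step: int = 4
    min_pixel_gap: int = 4
    crossings_per_row_trigger: int = 4
    bad_row_limit: int = 4
    equipment_regions: tuple[tuple[float, float, float, float], ...] = (
        (0.88, 1.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.solidity_threshold <= 1.0):
            raise ValueError("solidity_threshold must be in (0, 1]")
        for name in ("row_step", "min_pixel_gap", "crossings_per_row_trigger", "bad_row_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.solidity_min_area_px <= 0 or self.area_delta_trigger <= 0:
            raise ValueError("solidity_min_area_px and area_delta_trigger must be positive")


# ---------------------------------------------------------------------------
# contour extraction
# ---------------------------------------------------------------------------


def extract_contours(mask: BinaryMask) -> list[Contour]:
    """Trace the outer boundary of every connected foreground region.

    Regions use 8-connectivity; holes are irrelevant because only the outer
    boundary is traced.  Contours are returned largest-area first, ties broken
    by the topmost-then-leftmost starting point, so the ordering (and hence
    every downstream verdict) is deterministic.
    """
    fg = mask.foreground
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    contours: list[Contour] = []
    objects = ndimage.find_objects(labels)
    for lab, slc in zip(range(1, n + 1), objects):
        region = labels[slc] == lab
        filled = ndimage.binary_fill_holes(region)
        padded = np.pad(filled, 1).astype(float)
        traced = measure.find_contours(padded, 0.5)
        if not traced:
            continue
        # outer boundary = the longest loop of the filled region
        pts = max(traced, key=len)
        # undo padding and region-crop offsets
        pts = pts - 1.0 + np.array([slc[0].start, slc[1].start], dtype=float)
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        contours.append(Contour.from_points(pts))
    contours.sort(key=lambda c: (-c.area_px, c.points[:, 0].min(), c.points[:, 1].min()))
    return contours


# ---------------------------------------------------------------------------
# individual filters — each returns None on pass, or a rejection reason
# ---------------------------------------------------------------------------


def centroid_gate(
    contours: Sequence[Contour], image_shape: tuple[int, int], cfg: FilterConfig
) -> Optional[str]:
    """Reject when the candidate (largest) contour's centroid falls outside the
    configured fractional rectangle — equipment sits near image borders."""
    if not contours:
        return RejectReason.NO_CONTOUR
    h, w = image_shape
    r, c = contours[0].centroid_px
    r0, r1, c0, c1 = cfg.centroid_valid_box
    if not (r0 * h <= r <= r1 * h and c0 * w <= c <= c1 * w):
        return RejectReason.CENTROID
    return None


def connect_first_row(mask: BinaryMask) -> tuple[BinaryMask, Optional[int]]:
    """Draw a foreground line between the first and last foreground pixels of
    the topmost nonempty row.

    This re-closes a skin ring that intracranial noise has broken open, so the
    subsequent contour trace recovers the full outer boundary.  Returns the
    edited mask (a copy) and the connection row index, or the original mask and
    ``None`` when there is no foreground at all.  Only that single row is ever
    modified.
    """
    fg = mask.foreground
    rows = np.flatnonzero(fg.any(axis=1))
    if rows.size == 0:
        return mask, None
    r = int(rows[0])
    cols = np.flatnonzero(fg[r])
    pixels = mask.pixels.copy()
    pixels[r, cols[0] : cols[-1] + 1] = FOREGROUND
    return mask.with_pixels(pixels), r


def strip_connection_row(contour: Contour, row_index: int) -> Optional[Contour]:
    """Delete contour points lying on the connection row before projection.

    The synthetic line drawn by :func:`connect_first_row` is not anatomy, so
    every contour point within half a pixel of that row (the traced boundary
    runs along the row's upper edge at ``row - 0.5``) is dropped.  Point order
    is preserved.  Returns ``None`` when fewer than 3 points remain.
    """
    rows = contour.points[:, 0]
    keep = np.abs(rows - row_index) > 0.5 + 1e-12
    if keep.all():
        return contour
    pts = contour.points[keep]
    if len(pts) < 3:
        return None
    # geometry is recomputed on the surviving points
    return Contour.from_points(pts)


def solidity_check(contour: Contour, cfg: FilterConfig) -> Optional[str]:
    """Reject large contours whose solidity (area / convex-hull area) is below
    threshold; contours at or below the area gate are not tested, since small
    head cross-sections near the vertex are legitimately irregular."""
    if contour.area_px <= cfg.solidity_min_area_px:
        return None
    hull_area = contour.polygon().convex_hull.area
    if hull_area <= 0:
        return RejectReason.SOLIDITY
    solidity = contour.area_px / hull_area
    if solidity < cfg.solidity_threshold:
        return RejectReason.SOLIDITY
    return None


def four_direction_check(
    mask: BinaryMask,
    contour: Contour,
    prev_area_px: Optional[float],
    cfg: FilterConfig,
) -> Optional[str]:
    """Scan four cardinal rays from the contour centroid for foreground pixels
    outside the largest contour.

    Triggered only when the contour's area is *consistent* with the previous
    accepted slice (relative change within ``area_delta_trigger``): a largest
    contour misidentified because a discontinuity carved away part of the head
    tends to keep a plausible area while failing to enclose the full region.
    The first slice of a stack (no previous area) skips the check.
    """
    if prev_area_px is None or prev_area_px <= 0:
        return None
    rel = abs(contour.area_px - prev_area_px) / prev_area_px
    if rel > cfg.area_delta_trigger:
        return None

    h, w = mask.pixels.shape
    cr, cc = int(round(contour.centroid_px[0])), int(round(contour.centroid_px[1]))
    if not (0 <= cr < h and 0 <= cc < w):
        return RejectReason.FOUR_DIRECTION
    inside = polygon2mask((h, w), contour.points)
    # one-pixel dilation absorbs boundary-rasterisation rounding
    inside = ndimage.binary_dilation(inside, structure=np.ones((3, 3), dtype=bool))
    outside_fg = mask.foreground & ~inside
    if (
        outside_fg[cr, :].any()
        or outside_fg[:, cc].any()
    ):
        return RejectReason.FOUR_DIRECTION
    return None


def _boundary_pixels(contour: Contour) -> np.ndarray:
    """Integer pixel positions of the contour boundary (rounded vertices;
    consecutive traced vertices are <= 1 px apart, so rounding yields a
    connected chain)."""
    return np.unique(np.round(contour.points).astype(int), axis=0)


def row_crossing_check(
    contour: Contour, image_shape: tuple[int, int], cfg: FilterConfig
) -> Optional[str]:
    """Count well-separated boundary pixels on every ``row_step``-th image row.

    Within a scanned row, a boundary pixel counts when it lies at least
    ``min_pixel_gap`` columns from the previously *seen* boundary pixel (a
    contiguous tangent run therefore counts once).  A row with
    ``crossings_per_row_trigger`` or more counted pixels is a bad row; more
    than ``bad_row_limit`` bad rows reject the slice.  A convex contour has at
    most two well-separated crossings per row and always passes.
    """
    h, _ = image_shape
    bpx = _boundary_pixels(contour)
    bad_rows = 0
    for r in range(0, h, cfg.row_step):
        cols = np.sort(bpx[bpx[:, 0] == r, 1])
        if cols.size == 0:
            continue
        count = 1  # first pixel in the row always counts
        last = cols[0]
        for c in cols[1:]:
            if c - last >= cfg.min_pixel_gap:
                count += 1
            last = c
        if count >= cfg.crossings_per_row_trigger:
            bad_rows += 1
            if bad_rows > cfg.bad_row_limit:
                return RejectReason.ROW_CROSSING
    return None


def equipment_region_check(mask: BinaryMask, cfg: FilterConfig) -> Optional[str]:
    """Reject when any foreground pixel lies inside a configured equipment
    region (fractional rectangles, by default a full-width bottom band)."""
    h, w = mask.pixels.shape
    fg = mask.foreground
    for r0, r1, c0, c1 in cfg.equipment_regions:
        ri0, ri1 = int(np.floor(r0 * h)), int(np.ceil(r1 * h))
        ci0, ci1 = int(np.floor(c0 * w)), int(np.ceil(c1 * w))
        if fg[ri0:ri1, ci0:ci1].any():
            return RejectReason.EQUIPMENT
    return None


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def validate_slice(
    mask: BinaryMask,
    prev_area_px: Optional[float] = None,
    cfg: FilterConfig = FilterConfig(),
) -> SliceVerdict:
    """Run the full validity chain on one binary slice.

    Order: contour detection -> centroid gate -> largest contour -> first-row
    pixel connection -> re-trace -> largest -> strip connection row ->
    solidity -> four-direction (area-delta gated) -> row-crossing ->
    equipment-region.  The first failing filter determines the verdict; on
    success the validated outer-skin contour (connection row already stripped)
    is returned.
    """

    def reject(reason: str) -> SliceVerdict:
        return SliceVerdict(
            accepted=False, reason=reason, orientation=mask.orientation, index=mask.index
        )

    shape = mask.pixels.shape
    contours = extract_contours(mask)
    if not contours:
        return reject(RejectReason.NO_CONTOUR)

    fail = centroid_gate(contours, shape, cfg)
    if fail:
        return reject(fail)

    connected, conn_row = connect_first_row(mask)
    recontours = extract_contours(connected)
    if not recontours:
        return reject(RejectReason.NO_CONTOUR)
    largest = recontours[0]

    stripped = strip_connection_row(largest, conn_row) if conn_row is not None else largest
    if stripped is None:
        return reject(RejectReason.NO_CONTOUR)

    fail = solidity_check(stripped, cfg)
    if fail:
        return reject(fail)

    # the unstripped contour is the closed region used for outside-ness
    fail = four_direction_check(connected, largest, prev_area_px, cfg)
    if fail:
        return reject(fail)

    fail = row_crossing_check(stripped, shape, cfg)
    if fail:
        return reject(fail)

    fail = equipment_region_check(mask, cfg)
    if fail:
        return reject(fail)

    return SliceVerdict(
        accepted=True,
        reason=RejectReason.OK,
        contour=stripped,
        orientation=mask.orientation,
        index=mask.index,
    )
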