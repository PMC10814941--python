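"""High-frequency ultrasound lesion-shape analysis.

Two annotators outline the lesion independently; the consensus region of
interest is the pixelwise intersection of their masks (largest 8-connected
component).  Thirteen shape and size descriptors are then measured in
physical units (mm / mm²):

Area, Perimeter, Circularity (= 4·π·Area/Perimeter²), EquivDiameter
(diameter of the circle with the same area), Tortuosity (Perimeter/Area),
Eccentricity / MajorAxisLength / MinorAxisLength / Orientation of the
ellipse with the same normalized second central moments as the region,
FilledArea (area after hole filling), MaxFeretDiameter (maximum caliper
distance between boundary pixels) and MaxFeretAngle, and Solidity
(area / convex-hull area).

The perimeter is the literal boundary-chain length: the sum of Euclidean
distances between consecutive boundary pixels traced around the component
(steps of 1 or √2 pixels, scaled per-axis by the pixel spacing).
Orientation and MaxFeretAngle are counterclockwise-positive from the
horizontal image axis in (−90°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

__all__ = [
    "RoiMask",
    "US_FEATURES",
    "NoConsensusError",
    "consensus_roi",
    "shape_features",
    "trace_boundary",
    "extract_us_from_manifest",
]

#: Names of the 13 ultrasound shape feature columns, in output order.
US_FEATURES = (
    "Area",
    "Perimeter",
    "Circularity",
    "EquivDiameter",
    "Tortuosity",
    "Eccentricity",
    "MajorAxisLength",
    "MinorAxisLength",
    "Orientation",
    "FilledArea",
    "MaxFeretDiameter",
    "Solidity",
    "MaxFeretAngle",
)

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


class NoConsensusError(ValueError):
    """The two annotator masks have an empty intersection."""


@dataclass(frozen=True)
class RoiMask:
    """Binary lesion mask with (row, col) pixel spacing in mm."""

    mask: np.ndarray
    pixel_spacing_mm: tuple[float, float]

    def __post_init__(self):
        m = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("mask has no foreground pixels")
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def consensus_roi(mask_a: RoiMask, mask_b: RoiMask) -> RoiMask:
    """Pixelwise AND of two annotator masks, largest 8-connected component."""
    if mask_a.mask.shape != mask_b.mask.shape:
        raise ValueError("annotator masks must share the same grid")
    if not np.allclose(mask_a.pixel_spacing_mm, mask_b.pixel_spacing_mm):
        raise ValueError("annotator masks must share the same pixel spacing")
    inter = mask_a.mask & mask_b.mask
    if not inter.any():
        raise NoConsensusError("annotator masks do not overlap")
    return RoiMask(_largest_component(inter), mask_a.pixel_spacing_mm)


# Moore neighbourhood in clockwise order starting from the west neighbour.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary pixel chain of a single 8-connected component.

    Moore-neighbour tracing (clockwise) starting from the top-most of the
    left-most foreground pixels; the trace stops on the second arrival at the
    start pixel, so the region is assumed to have a simple outer boundary
    (true for the consensus lesion masks this package analyses).  Returns an
    ordered (n, 2) array of (row, col) boundary pixel coordinates; a
    single-pixel region returns that pixel alone.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start_idx = np.lexsort((rows, cols))[0]  # min col, then min row
    start = (int(rows[start_idx]), int(cols[start_idx]))

    boundary = [start]
    current = start
    # backtrack: the background neighbour the clockwise scan starts from;
    # the west neighbour of the start pixel is background by choice of start
    back = (start[0], start[1] - 1)
    max_steps = 4 * int(padded.size)
    for _ in range(max_steps):
        i0 = _MOORE.index((back[0] - current[0], back[1] - current[1]))
        nxt = None
        for k in range(1, 9):
            idx = (i0 + k) % 8
            cand = (current[0] + _MOORE[idx][0], current[1] + _MOORE[idx][1])
            if padded[cand]:
                # new backtrack: the background neighbour checked just before
                prev = (idx - 1) % 8
                back = (current[0] + _MOORE[prev][0], current[1] + _MOORE[prev][1])
                nxt = cand
                break
        if nxt is None:  # isolated pixel
            break
        current = nxt
        if current == start:
            break
        boundary.append(current)
    else:
        raise RuntimeError("boundary tracing failed to terminate")
    return np.asarray(boundary, dtype=int) - 1  # undo padding offset


def _moment_ellipse(
    coords_rc: np.ndarray, spacing: tuple[float, float]
) -> tuple[float, float, float, float]:
    """(major, minor, eccentricity, orientation_deg) of the moment ellipse.

    Uses the ellipse with the same normalized second central moments as the
    pixel region, computed in mm coordinates with the standard 1/12 pixel
    variance correction per axis.  Orientation is measured in an x-right /
    y-up frame (counterclockwise positive on screen).
    """
    sr, sc = spacing
    x = coords_rc[:, 1] * sc
    y = -coords_rc[:, 0] * sr  # flip rows so the angle is CCW-positive
    mxx = x.var(ddof=0) + sc**2 / 12.0
    myy = y.var(ddof=0) + sr**2 / 12.0
    mxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    common = np.sqrt((mxx - myy) ** 2 + 4 * mxy**2)
    l1 = (mxx + myy + common) / 2.0
    l2 = (mxx + myy - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    ecc = np.sqrt(1.0 - l2 / l1) if l1 > 0 else 0.0
    orientation = np.degrees(0.5 * np.arctan2(2 * mxy, mxx - myy))
    if orientation <= -90.0:
        orientation += 180.0
    elif orientation > 90.0:
        orientation -= 180.0
    return float(major), float(minor), float(ecc), float(orientation)


def _max_feret(points_xy: np.ndarray) -> tuple[float, float]:
    """Maximum pairwise distance among boundary points and its angle."""
    if len(points_xy) == 1:
        return 0.0, 0.0
    pts = points_xy
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    a, b = np.unravel_index(int(np.argmax(d2)), d2.shape)
    dx, dy = pts[b] - pts[a]
    angle = np.degrees(np.arctan2(dy, dx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(np.sqrt(d2[a, b])), float(angle)


def shape_features(roi: RoiMask) -> dict[str, float]:
    """Measure the 13 shape descriptors of a consensus ROI.

    Anisotropic pixel spacing is honoured: moments, boundary-step lengths and
    Feret distances are computed in mm coordinates, not pixel counts.
    """
    mask = _largest_component(roi.mask)
    sr, sc = roi.pixel_spacing_mm
    pixel_area = sr * sc
    n_px = int(mask.sum())
    if n_px < 5:
        raise ValueError(f"consensus ROI has only {n_px} pixels; too small to measure")

    area = n_px * pixel_area

    boundary = trace_boundary(mask)
    steps = np.diff(np.vstack([boundary, boundary[:1]]), axis=0).astype(float)
    steps[:, 0] *= sr
    steps[:, 1] *= sc
    perimeter = float(np.linalg.norm(steps, axis=1).sum())

    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    equiv_diameter = float(np.sqrt(4.0 * area / np.pi))
    tortuosity = perimeter / area

    coords = np.argwhere(mask)
    major, minor, ecc, orientation = _moment_ellipse(coords, (sr, sc))

    filled = ndimage.binary_fill_holes(mask)
    filled_area = float(filled.sum()) * pixel_area

    boundary_xy = np.column_stack(
        [boundary[:, 1] * sc, -boundary[:, 0].astype(float) * sr]
    )
    feret, feret_angle = _max_feret(boundary_xy)

    hull_px = int(convex_hull_image(mask).sum())
    solidity = n_px / hull_px

    return {
        "Area": float(area),
        "Perimeter": perimeter,
        "Circularity": float(circularity),
        "EquivDiameter": equiv_diameter,
        "Tortuosity": float(tortuosity),
        "Eccentricity": ecc,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Orientation": orientation,
        "FilledArea": filled_area,
        "MaxFeretDiameter": feret,
        "Solidity": float(solidity),
        "MaxFeretAngle": feret_angle,
    }


def extract_us_from_manifest(manifest_csv: str | Path) -> pd.DataFrame:
    """Run consensus + shape extraction over a two-annotator manifest.

    Expected columns: ``tumor_id, obs_idx, path_annotator1, path_annotator2,
    row_spacing_mm, col_spacing_mm``; mask paths (binary PNG) resolve
    relative to the manifest.
    """
    import imageio.v3 as iio

    manifest_csv = Path(manifest_csv)
    manifest = pd.read_csv(manifest_csv)
    base = manifest_csv.parent
    rows = []
    for rec in manifest.itertuples(index=False):
        spacing = (rec.row_spacing_mm, rec.col_spacing_mm)
        a = RoiMask(np.asarray(iio.imread(base / rec.path_annotator1)) > 0, spacing)
        b = RoiMask(np.asarray(iio.imread(base / rec.path_annotator2)) > 0, spacing)
        feats = shape_features(consensus_roi(a, b))
        rows.append({"tumor_id": rec.tumor_id, "obs_idx": rec.obs_idx, **feats})
    return pd.DataFrame(rows)
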