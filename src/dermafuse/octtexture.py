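"""OCT B-scan texture analysis: denoising, first-order statistics and
gray-level co-occurrence (Haralick) features.

The processing chain for an 8-bit B-scan is:

1. estimate a background threshold as mean + population standard deviation of
   a noise-only region below the tissue;
2. zero every pixel whose intensity is <= that threshold;
3. denoise with a 3×3 grayscale erosion followed by a 2-D Gaussian filter
   (σ = 1.5 px), re-quantized to 8-bit;
4. on a rectangular region of interest (ROI, at least 534 µm deep and 400 µm
   wide) compute four first-order statistics (mean, standard deviation,
   skewness, non-excess kurtosis) of the nonzero gray levels, and five
   Haralick features (energy, contrast, correlation, entropy, homogeneity)
   for each of 12 co-occurrence matrices (angles 0°/45°/90°/135° ×
   interpixel distances 1/5/9 px);
5. Shannon entropy of the ROI gray-level histogram is computed on the
   *original* (pre-denoising) scan.

Zero-intensity pixels are treated as background everywhere: they are
excluded from the first-order statistics, from the entropy histogram, and a
pixel pair enters a co-occurrence matrix only if both members are nonzero.
This yields the 65-element texture feature vector
(4 FOS + Shannon entropy + 12 GLCM × 5 Haralick).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BScan",
    "TextureROI",
    "GlcmConfig",
    "CoocMatrix",
    "DegenerateRoiError",
    "MIN_ROI_DEPTH_UM",
    "MIN_ROI_WIDTH_UM",
    "estimate_background_threshold",
    "threshold_filter",
    "denoise",
    "first_order_stats",
    "shannon_entropy",
    "compute_glcm",
    "haralick_features",
    "oct_feature_names",
    "extract_oct_features",
    "extract_oct_from_manifest",
]

MIN_ROI_DEPTH_UM = 534.0
MIN_ROI_WIDTH_UM = 400.0

HARALICK_NAMES = ("energy", "contrast", "correlation", "entropy", "homogeneity")
FOS_NAMES = ("fos_mean", "fos_std", "fos_skewness", "fos_kurtosis")


class DegenerateRoiError(ValueError):
    """ROI does not contain enough usable (nonzero) pixels."""


@dataclass(frozen=True)
class BScan:
    """8-bit OCT B-scan with physical pixel pitch metadata (µm/px)."""

    pixels: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("B-scan must be a 2-D image with >= 2 rows and cols")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("B-scan intensities must be within [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("pixel pitches must be positive")

    def replace_pixels(self, pixels: np.ndarray) -> "BScan":
        return BScan(pixels, self.axial_pitch_um, self.lateral_pitch_um)


@dataclass(frozen=True)
class TextureROI:
    """Rectangular analysis window, (row_offset, col_offset, height, width)."""

    row_offset: int
    col_offset: int
    height_px: int
    width_px: int

    def __post_init__(self):
        if min(self.row_offset, self.col_offset) < 0:
            raise ValueError("ROI offsets must be nonnegative")
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("ROI size must be positive")

    def validate(self, bscan: BScan, *, enforce_min_size: bool = False) -> None:
        rows, cols = bscan.pixels.shape
        if self.row_offset + self.height_px > rows or self.col_offset + self.width_px > cols:
            raise ValueError("ROI extends outside the B-scan")
        if enforce_min_size:
            depth = self.height_px * bscan.axial_pitch_um
            width = self.width_px * bscan.lateral_pitch_um
            if depth < MIN_ROI_DEPTH_UM or width < MIN_ROI_WIDTH_UM:
                raise ValueError(
                    f"ROI is {depth:.0f}x{width:.0f} um; must be at least "
                    f"{MIN_ROI_DEPTH_UM:.0f} um deep and {MIN_ROI_WIDTH_UM:.0f} um wide"
                )

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[
            self.row_offset : self.row_offset + self.height_px,
            self.col_offset : self.col_offset + self.width_px,
        ]


@dataclass(frozen=True)
class GlcmConfig:
    """Co-occurrence configuration.

    ``homogeneity_kernel`` selects between the inverse difference moment
    ``1/(1+(i−j)²)`` (default) and the ``1/(1+|i−j|)`` variant; ``log_base``
    sets the entropy base (2 = bits).
    """

    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    distances_px: tuple[int, ...] = (1, 5, 9)
    levels: int = 256
    symmetric: bool = True
    homogeneity_kernel: str = "squared"  # or "abs"
    log_base: float = 2.0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.homogeneity_kernel not in ("squared", "abs"):
            raise ValueError("homogeneity_kernel must be 'squared' or 'abs'")


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized gray-level co-occurrence matrix P_{d,θ}(i, j)."""

    p: np.ndarray
    angle_deg: int
    distance_px: int


# angle -> (row, col) offset per unit distance; rows increase downward, so
# 45° (up-right) has a negative row step.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def estimate_background_threshold(bscan: BScan, background: TextureROI) -> float:
    """Mean + population standard deviation of a noise-only region."""
    background.validate(bscan)
    vals = background.extract(bscan.pixels).astype(float)
    if vals.size == 0:
        raise ValueError("empty background region")
    return float(vals.mean() + vals.std(ddof=0))


def threshold_filter(bscan: BScan, threshold: float) -> BScan:
    """Zero every pixel with intensity <= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    px = bscan.pixels.copy()
    px[px <= threshold] = 0
    return bscan.replace_pixels(px)


def denoise(bscan: BScan, *, erosion_size: int = 3, sigma: float = 1.5) -> BScan:
    """3×3 grayscale erosion then Gaussian smoothing (σ = 1.5 px).

    The Gaussian kernel is truncated at 4σ and the result is rounded back to
    8-bit integers.
    """
    eroded = ndimage.grey_erosion(bscan.pixels, size=(erosion_size, erosion_size))
    smooth = ndimage.gaussian_filter(eroded.astype(float), sigma=sigma, truncate=4.0)
    return bscan.replace_pixels(np.clip(np.rint(smooth), 0, 255).astype(np.uint8))


def first_order_stats(
    bscan: BScan, roi: TextureROI
) -> tuple[float, float, float, float]:
    """Population mean/std/skewness/kurtosis of nonzero ROI gray levels.

    Kurtosis is non-excess (a normal distribution scores 3).  On a
    zero-variance ROI skewness and kurtosis are undefined and reported as 0
    with a warning.
    """
    roi.validate(bscan)
    vals = roi.extract(bscan.pixels).astype(float)
    vals = vals[vals > 0]
    if vals.size < 2:
        raise DegenerateRoiError(
            f"ROI has {vals.size} nonzero pixels; need at least 2"
        )
    mean = vals.mean()
    var = vals.var(ddof=0)
    std = np.sqrt(var)
    if var == 0:
        warnings.warn("zero-variance ROI: skewness/kurtosis undefined, reported as 0")
        return float(mean), 0.0, 0.0, 0.0
    centred = vals - mean
    skew = np.mean(centred**3) / std**3
    kurt = np.mean(centred**4) / var**2
    return float(mean), float(std), float(skew), float(kurt)


def shannon_entropy(bscan: BScan, roi: TextureROI, *, log_base: float = 2.0) -> float:
    """Shannon entropy of the 256-bin ROI gray-level histogram.

    Computed on the scan as given (use the *original* scan per the pipeline
    contract); zero-intensity background pixels are excluded.
    """
    roi.validate(bscan)
    vals = roi.extract(bscan.pixels).ravel()
    vals = vals[vals > 0]
    if vals.size == 0:
        raise DegenerateRoiError("ROI has no nonzero pixels")
    counts = np.bincount(vals, minlength=256).astype(float)
    q = counts[counts > 0] / vals.size
    return float(-(q * (np.log(q) / np.log(log_base))).sum())


def compute_glcm(
    bscan: BScan,
    roi: TextureROI,
    angle_deg: int,
    distance_px: int,
    levels: int = 256,
    *,
    symmetric: bool = True,
) -> CoocMatrix:
    """Gray-level co-occurrence matrix for one (angle, distance) offset.

    Ordered pixel pairs ``(p, p + offset)`` fully inside the ROI are counted
    when *both* members are nonzero; intensities above ``levels−1`` are not
    expected (8-bit input with ``levels=256``).  With ``symmetric=True`` the
    count matrix is added to its transpose before normalization to sum 1.
    """
    roi.validate(bscan)
    if angle_deg not in _ANGLE_OFFSETS:
        raise ValueError(f"unsupported angle {angle_deg}; use 0/45/90/135")
    if distance_px < 1:
        raise ValueError("distance must be >= 1 pixel")
    window = roi.extract(bscan.pixels)
    if levels < 256:
        window = (window.astype(np.int64) * levels) // 256
    else:
        window = window.astype(np.int64)
    dr, dc = (distance_px * o for o in _ANGLE_OFFSETS[angle_deg])
    h, w = window.shape
    # slice the window into "from" and "to" views shifted by (dr, dc)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no valid pixel pairs for angle {angle_deg} deg, distance {distance_px} px"
        )
    src = window[r0:r1, c0:c1]
    dst = window[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (src > 0) & (dst > 0)
    i = src[valid]
    j = dst[valid]
    if i.size == 0:
        raise ValueError(
            f"no nonzero pixel pairs for angle {angle_deg} deg, "
            f"distance {distance_px} px"
        )
    counts = np.bincount(i * levels + j, minlength=levels * levels).astype(float)
    counts = counts.reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    return CoocMatrix(counts / counts.sum(), angle_deg, distance_px)


def haralick_features(
    glcm: CoocMatrix,
    *,
    homogeneity_kernel: str = "squared",
    log_base: float = 2.0,
) -> tuple[float, float, float, float, float]:
    """(energy, contrast, correlation, entropy, homogeneity) of a GLCM.

    * energy = Σ p²
    * contrast = Σ (i−j)²·p
    * correlation = Σ (i−µ_i)(j−µ_j)·p / (σ_i·σ_j), defined as 1 when the
      marginal variance vanishes (single gray level)
    * entropy = −Σ p·log p (zero entries skipped; base ``log_base``)
    * homogeneity = Σ p / (1 + (i−j)²), or 1/(1+|i−j|) with the ``abs`` kernel
    """
    p = glcm.p
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"GLCM is not normalized (sum={total!r})")
    levels = p.shape[0]
    idx = np.arange(levels, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    diff = i - j

    energy = float((p**2).sum())
    contrast = float((diff**2 * p).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    var_i = float(((idx - mu_i) ** 2 * pi).sum())
    var_j = float(((idx - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        cov = float((((i - mu_i) * (j - mu_j)) * p).sum())
        correlation = cov / np.sqrt(var_i * var_j)

    nz = p[p > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(log_base))).sum())

    if homogeneity_kernel == "squared":
        homogeneity = float((p / (1.0 + diff**2)).sum())
    else:
        homogeneity = float((p / (1.0 + np.abs(diff))).sum())
    return energy, contrast, correlation, entropy, homogeneity


def oct_feature_names(cfg: GlcmConfig | None = None) -> list[str]:
    """The 65 OCT feature names in canonical order.

    Order: 4 FOS, ``shannon_entropy``, then for each Haralick feature ×
    angle × distance the name ``<feature>_a<angle>_d<distance>``.
    """
    cfg = cfg or GlcmConfig()
    names = list(FOS_NAMES) + ["shannon_entropy"]
    for feat in HARALICK_NAMES:
        for a in cfg.angles_deg:
            for d in cfg.distances_px:
                names.append(f"{feat}_a{a}_d{d}")
    return names


def extract_oct_features(
    bscan: BScan,
    roi: TextureROI,
    background: TextureROI,
    cfg: GlcmConfig | None = None,
    *,
    enforce_roi_size: bool = True,
) -> dict[str, float]:
    """Run the full OCT texture chain on one B-scan.

    Shannon entropy is measured on the raw scan; the threshold filter and
    denoising are applied before the FOS and GLCM stages.  Returns the
    65-element ordered name → value mapping.
    """
    cfg = cfg or GlcmConfig()
    roi.validate(bscan, enforce_min_size=enforce_roi_size)
    background.validate(bscan)

    out: dict[str, float] = {}
    entropy_raw = shannon_entropy(bscan, roi, log_base=cfg.log_base)

    thr = estimate_background_threshold(bscan, background)
    processed = denoise(threshold_filter(bscan, thr))

    mean, std, skew, kurt = first_order_stats(processed, roi)
    out["fos_mean"] = mean
    out["fos_std"] = std
    out["fos_skewness"] = skew
    out["fos_kurtosis"] = kurt
    out["shannon_entropy"] = entropy_raw

    values: dict[tuple[str, int, int], float] = {}
    for a in cfg.angles_deg:
        for d in cfg.distances_px:
            glcm = compute_glcm(
                processed, roi, a, d, cfg.levels, symmetric=cfg.symmetric
            )
            feats = haralick_features(
                glcm,
                homogeneity_kernel=cfg.homogeneity_kernel,
                log_base=cfg.log_base,
            )
            for name, val in zip(HARALICK_NAMES, feats):
                values[(name, a, d)] = val
    for feat in HARALICK_NAMES:
        for a in cfg.angles_deg:
            for d in cfg.distances_px:
                out[f"{feat}_a{a}_d{d}"] = values[(feat, a, d)]
    return out


def extract_oct_from_manifest(
    manifest_csv: str | Path, cfg: GlcmConfig | None = None
) -> pd.DataFrame:
    """Run OCT extraction over an annotation manifest.

    Expected columns: ``tumor_id, obs_idx, path, roi_row, roi_col, roi_h,
    roi_w, bg_row, bg_col, bg_h, bg_w, axial_um, lateral_um``; image paths
    (8-bit grayscale PNG/TIFF) resolve relative to the manifest.
    """
    import imageio.v3 as iio

    manifest_csv = Path(manifest_csv)
    manifest = pd.read_csv(manifest_csv)
    base = manifest_csv.parent
    rows = []
    for rec in manifest.itertuples(index=False):
        img = np.asarray(iio.imread(base / rec.path))
        scan = BScan(img, rec.axial_um, rec.lateral_um)
        roi = TextureROI(rec.roi_row, rec.roi_col, rec.roi_h, rec.roi_w)
        bg = TextureROI(rec.bg_row, rec.bg_col, rec.bg_h, rec.bg_w)
        feats = extract_oct_features(scan, roi, bg, cfg)
        rows.append({"tumor_id": rec.tumor_id, "obs_idx": rec.obs_idx, **feats})
    return pd.DataFrame(rows)
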