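"""Seeded synthetic multimodal cohorts for end-to-end testing.

The generator emulates the statistical structure — not the physics — of the
three measurement channels:

* **Spectra** are built in optical-density space on a 450–950 nm grid (1 nm
  pitch): a flat baseline plus a melanin ramp (raising OD below 620 nm and
  decaying to zero by 700 nm, so the melanin index responds linearly), two
  Gaussian hemoglobin absorption dips at 545 and 575 nm (driving the
  erythema and hemoglobin indices), a near-infrared reflectance tilt over
  650–950 nm (driving the linearity slope) and additive Gaussian reflectance
  noise.  Healthy-skin spectra use fixed mild baseline chromophore values.
* **OCT B-scans** are Gaussian random fields with a class-dependent
  correlation length and contrast, shifted to a class mean intensity, sitting
  above a pure-noise background strip used for threshold estimation.
* **Ultrasound mask pairs** are rasterized ellipses of given size and
  eccentricity with smooth radial boundary roughness; the two annotator
  masks differ by small independent boundary jitter.

Two named parameter presets exist: ``"well-separated"`` encodes strong
between-class differences (following the ordinal relations of the real
cohort: melanin highest for benign and pigmented lesions, erythema and
hemoglobin highest for nodular and lowest for superficial forms, circularity
high for benign and low for superficial forms), and ``"overlapping"``
compresses every class parameter 70% toward the across-class mean and
doubles the noise scales.  Default cohort composition mirrors the study:
37 tumors (2/2/15/3/5/10 per class), 10 observations each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fusion import DIAGNOSIS_LABELS
from .octtexture import BScan, TextureROI
from .spectra import ReflectanceSpectrum
from .ultrasound import RoiMask

__all__ = [
    "ClassGeneratorParams",
    "CohortSpec",
    "HEALTHY_PARAMS",
    "WELL_SEPARATED",
    "OVERLAPPING",
    "preset",
    "DEFAULT_TUMORS_PER_CLASS",
    "generate_spectrum",
    "generate_bscan",
    "generate_mask_pair",
    "generate_cohort",
    "simulate_modalities",
]


@dataclass(frozen=True)
class ClassGeneratorParams:
    """Per-class knobs of the synthetic generator.

    Each knob moves one downstream feature family monotonically:
    ``melanin_slope`` (OD units) the melanin index, ``hemoglobin_dip_depth``
    (OD units) the erythema/hemoglobin indices, ``nir_slope`` (reflectance
    per nm) the linearity slope, ``texture_correlation_length_px`` /
    ``texture_contrast`` / ``mean_intensity`` the OCT texture features, and
    ``shape_eccentricity`` / ``boundary_roughness`` / ``size_mm`` (major-axis
    diameter) the ultrasound shape descriptors.
    """

    melanin_slope: float
    hemoglobin_dip_depth: float
    nir_slope: float
    texture_correlation_length_px: float
    texture_contrast: float
    mean_intensity: float
    shape_eccentricity: float
    boundary_roughness: float
    size_mm: float
    noise_sd_spectrum: float = 0.004
    annotator_jitter: float = 0.02
    tumor_scale_sd: float = 0.05  # lognormal sd of per-tumor parameter jitter
    obs_scale_sd: float = 0.10  # lognormal sd of per-acquisition jitter (OCT/US)


#: Fixed mild chromophore values used for every healthy-skin spectrum.
HEALTHY_PARAMS = ClassGeneratorParams(
    melanin_slope=0.05,
    hemoglobin_dip_depth=0.05,
    nir_slope=-1e-4,
    texture_correlation_length_px=3.0,
    texture_contrast=15.0,
    mean_intensity=120.0,
    shape_eccentricity=0.3,
    boundary_roughness=0.1,
    size_mm=4.0,
)

WELL_SEPARATED: dict[str, ClassGeneratorParams] = {
    "benign": ClassGeneratorParams(
        melanin_slope=0.30, hemoglobin_dip_depth=0.10, nir_slope=-2.0e-4,
        texture_correlation_length_px=6.0, texture_contrast=12.0,
        mean_intensity=150.0, shape_eccentricity=0.20,
        boundary_roughness=0.05, size_mm=4.0,
    ),
    "pigmented_bcc": ClassGeneratorParams(
        melanin_slope=0.35, hemoglobin_dip_depth=0.12, nir_slope=-1.0e-4,
        texture_correlation_length_px=2.0, texture_contrast=30.0,
        mean_intensity=120.0, shape_eccentricity=0.50,
        boundary_roughness=0.15, size_mm=3.0,
    ),
    "nodular_bcc": ClassGeneratorParams(
        melanin_slope=0.10, hemoglobin_dip_depth=0.40, nir_slope=-3.0e-4,
        texture_correlation_length_px=4.0, texture_contrast=20.0,
        mean_intensity=180.0, shape_eccentricity=0.55,
        boundary_roughness=0.20, size_mm=5.0,
    ),
    "superficial_bcc": ClassGeneratorParams(
        melanin_slope=0.08, hemoglobin_dip_depth=0.04, nir_slope=-0.5e-4,
        texture_correlation_length_px=1.5, texture_contrast=35.0,
        mean_intensity=100.0, shape_eccentricity=0.85,
        boundary_roughness=0.30, size_mm=6.0,
    ),
    "infiltrative_ulcerative_bcc": ClassGeneratorParams(
        melanin_slope=0.15, hemoglobin_dip_depth=0.22, nir_slope=-4.0e-4,
        texture_correlation_length_px=8.0, texture_contrast=15.0,
        mean_intensity=135.0, shape_eccentricity=0.70,
        boundary_roughness=0.45, size_mm=7.0,
    ),
    "morpheaform_bcc": ClassGeneratorParams(
        melanin_slope=0.05, hemoglobin_dip_depth=0.16, nir_slope=-1.5e-4,
        texture_correlation_length_px=3.0, texture_contrast=8.0,
        mean_intensity=200.0, shape_eccentricity=0.40,
        boundary_roughness=0.10, size_mm=2.5,
    ),
}

_COMPRESSIBLE = (
    "melanin_slope", "hemoglobin_dip_depth", "nir_slope",
    "texture_correlation_length_px", "texture_contrast", "mean_intensity",
    "shape_eccentricity", "boundary_roughness", "size_mm",
)


def _compress(table: Mapping[str, ClassGeneratorParams], keep: float, noise_mult: float):
    """Shrink class differences toward the across-class mean."""
    means = {
        f: float(np.mean([getattr(p, f) for p in table.values()]))
        for f in _COMPRESSIBLE
    }
    out = {}
    for label, p in table.items():
        kw = {f: means[f] + keep * (getattr(p, f) - means[f]) for f in _COMPRESSIBLE}
        out[label] = replace(
            p,
            **kw,
            noise_sd_spectrum=p.noise_sd_spectrum * noise_mult,
            annotator_jitter=p.annotator_jitter * noise_mult,
            tumor_scale_sd=p.tumor_scale_sd * noise_mult * 2,
            obs_scale_sd=p.obs_scale_sd * noise_mult,
        )
    return out


#: Classes barely separated: 30% of the well-separated contrasts, doubled noise.
OVERLAPPING: dict[str, ClassGeneratorParams] = _compress(
    WELL_SEPARATED, keep=0.30, noise_mult=2.0
)


def preset(name: str) -> dict[str, ClassGeneratorParams]:
    """Return a named class-parameter preset."""
    table = {"well-separated": WELL_SEPARATED, "overlapping": OVERLAPPING}
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; use {sorted(table)}")
    return table[name]


#: Class composition of the default cohort (mirrors the study inventory).
DEFAULT_TUMORS_PER_CLASS: dict[str, int] = {
    "infiltrative_ulcerative_bcc": 2,
    "pigmented_bcc": 2,
    "superficial_bcc": 15,
    "morpheaform_bcc": 3,
    "nodular_bcc": 5,
    "benign": 10,
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition: tumors per class, observations per tumor, seed."""

    tumors_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TUMORS_PER_CLASS)
    )
    observations_per_tumor: int = 10
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.tumors_per_class) - set(DIAGNOSIS_LABELS)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        if sum(self.tumors_per_class.values()) < len(self.tumors_per_class):
            raise ValueError("need at least one tumor per represented class")
        if self.observations_per_tumor < 1:
            raise ValueError("observations_per_tumor must be >= 1")


# ---------------------------------------------------------------------------
# Spectra

_WL = np.arange(450.0, 951.0, 1.0)
_BASE_OD = 0.30


def generate_spectrum(
    params: ClassGeneratorParams,
    site: str,
    rng: np.random.Generator,
) -> ReflectanceSpectrum:
    """Draw one synthetic diffuse-reflectance spectrum.

    ``site="healthy"`` ignores the class chromophore values and uses the
    fixed :data:`HEALTHY_PARAMS` baseline (with the class noise level).
    """
    p = HEALTHY_PARAMS if site == "healthy" else params
    wl = _WL
    melanin_ramp = np.clip((700.0 - wl) / 80.0, 0.0, 1.0)  # 1 below 620, 0 above 700
    dips = np.exp(-((wl - 545.0) ** 2) / (2 * 12.0**2)) + 0.8 * np.exp(
        -((wl - 575.0) ** 2) / (2 * 12.0**2)
    )
    od = _BASE_OD + p.melanin_slope * melanin_ramp + p.hemoglobin_dip_depth * dips
    reflectance = 10.0 ** (-od)
    reflectance = reflectance + p.nir_slope * np.clip(wl - 650.0, 0.0, None)
    reflectance = reflectance + rng.normal(0.0, params.noise_sd_spectrum, wl.size)
    if np.any(reflectance <= 0):
        raise ValueError("generator parameters produced nonpositive reflectance")
    return ReflectanceSpectrum(wl, reflectance, site=site)


# ---------------------------------------------------------------------------
# OCT B-scans

# geometry chosen once: pitches follow the device class; the ROI comfortably
# satisfies the >= 534 x 400 um minimum at these pitches
AXIAL_PITCH_UM = 5.34
LATERAL_PITCH_UM = 7.32
_TISSUE_ROWS, _BG_ROWS, _COLS = 120, 30, 72
_ROI = TextureROI(row_offset=8, col_offset=6, height_px=104, width_px=60)
_BG_REGION = TextureROI(row_offset=_TISSUE_ROWS + 2, col_offset=2,
                        height_px=_BG_ROWS - 4, width_px=_COLS - 4)


def _gaussian_field(shape, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    from scipy import ndimage

    white = rng.standard_normal(shape)
    if corr_len <= 0.5:
        field_ = white
    else:
        field_ = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_bscan(
    params: ClassGeneratorParams, rng: np.random.Generator
) -> tuple[BScan, TextureROI, TextureROI]:
    """Draw one synthetic B-scan plus its analysis and background regions.

    The tissue block is a unit-variance Gaussian random field with the class
    correlation length, scaled by the class contrast and shifted to the class
    mean intensity; a low-intensity pure-noise strip below the tissue serves
    as the threshold-estimation region.
    """
    tissue = _gaussian_field((_TISSUE_ROWS, _COLS),
                             params.texture_correlation_length_px, rng)
    tissue = params.mean_intensity + params.texture_contrast * tissue
    background = np.abs(rng.normal(6.0, 2.5, (_BG_ROWS, _COLS)))
    img = np.clip(np.rint(np.vstack([tissue, background])), 0, 255).astype(np.uint8)
    scan = BScan(img, AXIAL_PITCH_UM, LATERAL_PITCH_UM)
    return scan, _ROI, _BG_REGION


# ---------------------------------------------------------------------------
# Ultrasound mask pairs

_MASK_SIZE = 192
MASK_SPACING_MM = (0.06, 0.06)
_N_HARMONICS = 5


def _radial_profile(
    theta: np.ndarray, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth 2π-periodic perturbation with RMS ~ ``amplitude``."""
    if amplitude <= 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for k in range(2, 2 + _N_HARMONICS):
        a, b = rng.normal(0.0, 1.0, 2)
        out += a * np.cos(k * theta) + b * np.sin(k * theta)
    return amplitude * out / np.sqrt(_N_HARMONICS)


def generate_mask_pair(
    params: ClassGeneratorParams, rng: np.random.Generator
) -> tuple[RoiMask, RoiMask]:
    """Draw the two annotator masks of one synthetic ultrasound lesion.

    A base ellipse (major-axis diameter ``size_mm``, eccentricity
    ``shape_eccentricity``, random orientation) has its boundary radius
    modulated by smooth periodic roughness; each annotator's mask adds small
    independent boundary jitter, so the pair overlaps but is not identical.
    """
    sr, sc = MASK_SPACING_MM
    a = params.size_mm / 2.0  # semi-major axis, mm
    if a <= 2 * max(sr, sc):
        raise ValueError(f"size_mm={params.size_mm} too small for the mask grid")
    e = float(np.clip(params.shape_eccentricity, 0.0, 0.95))
    b = a * np.sqrt(1.0 - e**2)
    phi = rng.uniform(-np.pi / 2, np.pi / 2)

    center = (_MASK_SIZE / 2.0, _MASK_SIZE / 2.0)
    rows, cols = np.mgrid[0:_MASK_SIZE, 0:_MASK_SIZE]
    x = (cols - center[1]) * sc
    y = -(rows - center[0]) * sr
    xr = x * np.cos(phi) + y * np.sin(phi)
    yr = -x * np.sin(phi) + y * np.cos(phi)
    theta = np.arctan2(yr / b, xr / a)  # elliptical angle parameter
    r_ellipse = np.sqrt((np.cos(theta) * a) ** 2 + (np.sin(theta) * b) ** 2)
    r_pixel = np.sqrt(xr**2 + yr**2)

    base_rough = _radial_profile(theta, params.boundary_roughness, rng)
    masks = []
    for _ in range(2):
        jitter = _radial_profile(theta, params.annotator_jitter, rng)
        # clip the radial modulation so very rough lesions stay star-shaped
        # and inside the field of view
        boundary = r_ellipse * np.clip(1.0 + base_rough + jitter, 0.4, 1.45)
        masks.append(RoiMask(r_pixel <= boundary, MASK_SPACING_MM))
    return masks[0], masks[1]


# ---------------------------------------------------------------------------
# Cohort assembly

def _tumor_params(
    base: ClassGeneratorParams, rng: np.random.Generator
) -> ClassGeneratorParams:
    """Per-tumor biological variability: lognormal jitter of each knob."""
    sd = base.tumor_scale_sd

    def jit(v):
        return v * float(rng.lognormal(0.0, sd))

    return replace(
        base,
        melanin_slope=jit(base.melanin_slope),
        hemoglobin_dip_depth=jit(base.hemoglobin_dip_depth),
        nir_slope=jit(base.nir_slope),
        texture_correlation_length_px=jit(base.texture_correlation_length_px),
        texture_contrast=jit(base.texture_contrast),
        mean_intensity=float(np.clip(jit(base.mean_intensity), 40.0, 230.0)),
        shape_eccentricity=float(
            np.clip(base.shape_eccentricity + rng.normal(0.0, sd), 0.0, 0.95)
        ),
        boundary_roughness=jit(base.boundary_roughness),
        size_mm=float(np.clip(jit(base.size_mm), 1.5, 8.5)),
    )


def _obs_params(
    p: ClassGeneratorParams, rng: np.random.Generator
) -> ClassGeneratorParams:
    """Per-acquisition variability of the imaging knobs.

    Repeated OCT/ultrasound acquisitions of the same tumor are taken at
    different sites and probe positions, so texture gain and apparent lesion
    geometry vary between observations; without this spread every tumor
    would collapse to a point in feature space.
    """
    sd = p.obs_scale_sd

    def jit(v):
        return v * float(rng.lognormal(0.0, sd))

    return replace(
        p,
        texture_contrast=jit(p.texture_contrast),
        texture_correlation_length_px=jit(p.texture_correlation_length_px),
        mean_intensity=float(np.clip(jit(p.mean_intensity), 40.0, 230.0)),
        size_mm=float(np.clip(jit(p.size_mm), 1.5, 8.5)),
        shape_eccentricity=float(
            np.clip(p.shape_eccentricity + rng.normal(0.0, sd / 2), 0.0, 0.95)
        ),
    )


def _iter_tumors(spec: CohortSpec):
    i = 0
    for label in DIAGNOSIS_LABELS:
        for _ in range(spec.tumors_per_class.get(label, 0)):
            i += 1
            yield f"t{i:02d}", label


def simulate_modalities(
    spec: CohortSpec, params_table: Mapping[str, ClassGeneratorParams] | str = "well-separated"
):
    """Generate a cohort fully in memory and run the three feature extractors.

    Returns ``(drs, oct, us, labels)`` data frames in the same schema the
    file-based manifest extractors produce.  Deterministic given
    ``spec.seed``.
    """
    from .octtexture import extract_oct_features
    from .spectra import extract_drs_features
    from .ultrasound import consensus_roi, shape_features

    if isinstance(params_table, str):
        params_table = preset(params_table)
    rng = np.random.default_rng(spec.seed)
    drs_rows, oct_rows, us_rows, label_rows = [], [], [], []
    for tumor_id, label in _iter_tumors(spec):
        p = _tumor_params(params_table[label], rng)
        label_rows.append({"tumor_id": tumor_id, "label": label})
        n = spec.observations_per_tumor

        lesions = [generate_spectrum(p, "lesion", rng) for _ in range(n)]
        healthy = [generate_spectrum(p, "healthy", rng) for _ in range(n)]
        feats = extract_drs_features(lesions, healthy)
        feats.insert(0, "tumor_id", tumor_id)
        feats.insert(1, "obs_idx", np.arange(n))
        drs_rows.append(feats)

        for k in range(n):
            op = _obs_params(p, rng)
            scan, roi, bg = generate_bscan(op, rng)
            oct_rows.append(
                {"tumor_id": tumor_id, "obs_idx": k,
                 **extract_oct_features(scan, roi, bg)}
            )
            ma, mb = generate_mask_pair(op, rng)
            us_rows.append(
                {"tumor_id": tumor_id, "obs_idx": k,
                 **shape_features(consensus_roi(ma, mb))}
            )
    return (
        pd.concat(drs_rows, ignore_index=True),
        pd.DataFrame(oct_rows),
        pd.DataFrame(us_rows),
        pd.DataFrame(label_rows),
    )


def generate_cohort(
    spec: CohortSpec,
    params_table: Mapping[str, ClassGeneratorParams] | str,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a full synthetic cohort in the pipeline's on-disk input formats.

    Produces per-spectrum CSVs, 8-bit PNG B-scans, binary PNG mask pairs,
    the three modality manifests and the labels CSV; byte-reproducible from
    ``spec.seed``.  Returns the manifest paths.
    """
    import imageio.v3 as iio

    if isinstance(params_table, str):
        params_table = preset(params_table)
    out = Path(out_dir)
    for sub in ("spectra", "oct", "us"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    drs_manifest, oct_manifest, us_manifest, label_rows = [], [], [], []
    for tumor_id, label in _iter_tumors(spec):
        p = _tumor_params(params_table[label], rng)
        label_rows.append({"tumor_id": tumor_id, "label": label})
        for k in range(spec.observations_per_tumor):
            for site in ("lesion", "healthy"):
                s = generate_spectrum(p, site, rng)
                rel = f"spectra/{tumor_id}_{site}_{k:02d}.csv"
                pd.DataFrame(
                    {"wavelength_nm": s.wavelengths_nm, "reflectance": s.reflectance}
                ).to_csv(out / rel, index=False)
                drs_manifest.append(
                    {"tumor_id": tumor_id, "site": site, "path": rel}
                )
            op = _obs_params(p, rng)
            scan, roi, bg = generate_bscan(op, rng)
            rel = f"oct/{tumor_id}_{k:02d}.png"
            iio.imwrite(out / rel, scan.pixels)
            oct_manifest.append({
                "tumor_id": tumor_id, "obs_idx": k, "path": rel,
                "roi_row": roi.row_offset, "roi_col": roi.col_offset,
                "roi_h": roi.height_px, "roi_w": roi.width_px,
                "bg_row": bg.row_offset, "bg_col": bg.col_offset,
                "bg_h": bg.height_px, "bg_w": bg.width_px,
                "axial_um": scan.axial_pitch_um, "lateral_um": scan.lateral_pitch_um,
            })
            ma, mb = generate_mask_pair(op, rng)
            rel_a = f"us/{tumor_id}_{k:02d}_annotator1.png"
            rel_b = f"us/{tumor_id}_{k:02d}_annotator2.png"
            iio.imwrite(out / rel_a, (ma.mask * np.uint8(255)))
            iio.imwrite(out / rel_b, (mb.mask * np.uint8(255)))
            us_manifest.append({
                "tumor_id": tumor_id, "obs_idx": k,
                "path_annotator1": rel_a, "path_annotator2": rel_b,
                "row_spacing_mm": MASK_SPACING_MM[0],
                "col_spacing_mm": MASK_SPACING_MM[1],
            })

    paths = {
        "drs_manifest": out / "drs_manifest.csv",
        "oct_manifest": out / "oct_manifest.csv",
        "us_manifest": out / "us_manifest.csv",
        "labels": out / "labels.csv",
    }
    pd.DataFrame(drs_manifest).to_csv(paths["drs_manifest"], index=False)
    pd.DataFrame(oct_manifest).to_csv(paths["oct_manifest"], index=False)
    pd.DataFrame(us_manifest).to_csv(paths["us_manifest"], index=False)
    pd.DataFrame(label_rows).to_csv(paths["labels"], index=False)
    return paths
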