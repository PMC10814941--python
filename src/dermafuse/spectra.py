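"""Diffuse-reflectance spectroscopy (DRS) feature extraction.

A diffuse-reflectance spectrum is the wavelength-resolved fraction of light
reflected by skin relative to a near-100% reference.  From each lesion
spectrum six coefficients are derived:

* ``M`` — melanin pigmentation index, ``100·(OD620 − OD700)``;
* ``E`` — erythema index (Dawson grouping),
  ``100·[OD560 + 1.5·(OD545 + OD575) − 2·(OD510 + OD610)]``;
* ``H`` — hemoglobin content,
  ``(OD545 − OD529)/16 − (OD570 − OD545)/25``;
* ``Linearity`` — OLS slope of reflectance vs wavelength on 650–800 nm;
* ``Error_linearity`` — RMS of the residuals of that fit;
* ``Rt`` — malignancy coefficient, a two-wavelength lesion/healthy
  reflectance ratio at 500 and 700 nm.

``OD`` denotes the effective optical density ``−log10(R)``.  To remove
individual skin differences, M/E/H/Linearity/Error_linearity of a lesion are
normalized by the mean of the same coefficient over the volunteer's healthy
spectra; ``Rt`` is intrinsically a lesion-vs-healthy contrast and is not
re-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReflectanceSpectrum",
    "OpticalDensitySpectrum",
    "DRS_FEATURES",
    "InvalidSpectrumError",
    "ZeroHealthyCoefficientError",
    "to_optical_density",
    "sample_od",
    "sample_reflectance",
    "melanin_index",
    "erythema_index",
    "hemoglobin_index",
    "linearity_fit",
    "malignancy_coefficient",
    "extract_drs_features",
    "read_spectrum_csv",
    "extract_drs_from_manifest",
]

#: Names of the six DRS-derived feature columns, in output order.
DRS_FEATURES = ("M", "E", "H", "Linearity", "Error_linearity", "Rt")

#: Wavelength window (nm) of the linearity fit.
LINEARITY_WINDOW = (650.0, 800.0)


class InvalidSpectrumError(ValueError):
    """Raised for spectra violating the reflectance-spectrum contract."""


class ZeroHealthyCoefficientError(ZeroDivisionError):
    """Raised when a healthy-skin mean coefficient is too close to zero to
    normalize by."""


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Wavelength-indexed diffuse reflectance relative to a ~100% reference.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres covering at least
        [500, 800] nm.
    reflectance : array-like
        Reflectance ratios, strictly positive (small excursions above 1 from
        noise are tolerated).
    site : {"lesion", "healthy"}
        Acquisition site tag.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    site: str = "lesion"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", r)
        if wl.ndim != 1 or r.ndim != 1 or wl.size != r.size or wl.size < 2:
            raise InvalidSpectrumError(
                "wavelengths and reflectance must be 1-D of equal length >= 2"
            )
        if not np.all(np.diff(wl) > 0):
            raise InvalidSpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise InvalidSpectrumError(
                "reflectance must be finite and strictly positive"
            )
        if self.site not in ("lesion", "healthy"):
            raise InvalidSpectrumError(f"unknown site tag {self.site!r}")


@dataclass(frozen=True)
class OpticalDensitySpectrum:
    """Effective optical density ``od = −log10(reflectance)``."""

    wavelengths_nm: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "wavelengths_nm", np.asarray(self.wavelengths_nm, dtype=float)
        )
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))


def to_optical_density(spectrum: ReflectanceSpectrum) -> OpticalDensitySpectrum:
    """Convert a reflectance spectrum to effective optical density."""
    return OpticalDensitySpectrum(
        wavelengths_nm=spectrum.wavelengths_nm,
        od=-np.log10(spectrum.reflectance),
    )


def _interp(wl_grid: np.ndarray, values: np.ndarray, wavelength_nm: float) -> float:
    if wavelength_nm < wl_grid[0] or wavelength_nm > wl_grid[-1]:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside spectrum range "
            f"[{wl_grid[0]}, {wl_grid[-1]}] nm"
        )
    return float(np.interp(wavelength_nm, wl_grid, values))


def sample_od(od: OpticalDensitySpectrum, wavelength_nm: float) -> float:
    """Linearly interpolated optical density at ``wavelength_nm``."""
    return _interp(od.wavelengths_nm, od.od, wavelength_nm)


def sample_reflectance(spectrum: ReflectanceSpectrum, wavelength_nm: float) -> float:
    """Linearly interpolated reflectance at ``wavelength_nm``."""
    return _interp(spectrum.wavelengths_nm, spectrum.reflectance, wavelength_nm)


def melanin_index(od: OpticalDensitySpectrum) -> float:
    """Melanin pigmentation index ``M = 100·(OD620 − OD700)``."""
    return 100.0 * (sample_od(od, 620.0) - sample_od(od, 700.0))


def erythema_index(od: OpticalDensitySpectrum) -> float:
    """Erythema index with the Dawson grouping.

    ``E = 100·[OD560 + 1.5·(OD545 + OD575) − 2·(OD510 + OD610)]``.  The
    coefficients sum to zero, so a flat spectrum scores exactly 0.
    """
    od510 = sample_od(od, 510.0)
    od545 = sample_od(od, 545.0)
    od560 = sample_od(od, 560.0)
    od575 = sample_od(od, 575.0)
    od610 = sample_od(od, 610.0)
    return 100.0 * (od560 + 1.5 * (od545 + od575) - 2.0 * (od510 + od610))


def hemoglobin_index(od: OpticalDensitySpectrum) -> float:
    """Hemoglobin content ``H = (OD545 − OD529)/16 − (OD570 − OD545)/25``."""
    od529 = sample_od(od, 529.0)
    od545 = sample_od(od, 545.0)
    od570 = sample_od(od, 570.0)
    return (od545 - od529) / 16.0 - (od570 - od545) / 25.0


def linearity_fit(spectrum: ReflectanceSpectrum) -> tuple[float, float]:
    """OLS line fit of reflectance vs wavelength restricted to 650–800 nm.

    Returns
    -------
    slope : float
        Fitted slope (reflectance per nm).
    rms_residual : float
        Root-mean-square of the fit residuals (dimensionless).
    """
    lo, hi = LINEARITY_WINDOW
    sel = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
    if int(sel.sum()) < 3:
        raise ValueError(
            f"need >= 3 samples in [{lo}, {hi}] nm for the linearity fit, "
            f"got {int(sel.sum())}"
        )
    x = spectrum.wavelengths_nm[sel]
    y = spectrum.reflectance[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(np.sqrt(np.mean(resid**2)))


def malignancy_coefficient(
    lesion: ReflectanceSpectrum, healthy: ReflectanceSpectrum
) -> float:
    """Malignancy coefficient ``Rt``.

    ``Rt = (R_healthy(500)·R_lesion(700)) / (R_healthy(700)·R_lesion(500))``;
    identical spectra give exactly 1 and swapping the roles inverts it.
    """
    rh500 = sample_reflectance(healthy, 500.0)
    rh700 = sample_reflectance(healthy, 700.0)
    rn500 = sample_reflectance(lesion, 500.0)
    rn700 = sample_reflectance(lesion, 700.0)
    return (rh500 * rn700) / (rh700 * rn500)


def _coefficients(spectrum: ReflectanceSpectrum) -> dict[str, float]:
    od = to_optical_density(spectrum)
    slope, rms = linearity_fit(spectrum)
    return {
        "M": melanin_index(od),
        "E": erythema_index(od),
        "H": hemoglobin_index(od),
        "Linearity": slope,
        "Error_linearity": rms,
    }


def mean_spectrum(spectra: Sequence[ReflectanceSpectrum]) -> ReflectanceSpectrum:
    """Pointwise mean reflectance on the grid of the first spectrum.

    Spectra on different grids are linearly interpolated onto that grid.
    """
    ref = spectra[0]
    grid = ref.wavelengths_nm
    stack = np.stack(
        [
            s.reflectance
            if s.wavelengths_nm.shape == grid.shape
            and np.allclose(s.wavelengths_nm, grid)
            else np.interp(grid, s.wavelengths_nm, s.reflectance)
            for s in spectra
        ]
    )
    return ReflectanceSpectrum(grid, stack.mean(axis=0), site=ref.site)


def extract_drs_features(
    lesion_spectra: Sequence[ReflectanceSpectrum],
    healthy_spectra: Sequence[ReflectanceSpectrum],
    *,
    zero_mean_epsilon: float = 0.0,
) -> pd.DataFrame:
    """Per-lesion-spectrum feature rows, normalized to healthy skin.

    Each of M/E/H/Linearity/Error_linearity is divided by the mean of the
    same coefficient over ``healthy_spectra``; ``Rt`` is computed against the
    pointwise mean healthy spectrum and not re-normalized.

    Parameters
    ----------
    zero_mean_epsilon : float
        If a healthy mean coefficient has absolute value <= this threshold a
        :class:`ZeroHealthyCoefficientError` naming the coefficient is
        raised.  The default 0.0 only rejects an exactly-zero mean.

    Returns
    -------
    pandas.DataFrame
        One row per lesion spectrum with columns ``M, E, H, Linearity,
        Error_linearity, Rt``.
    """
    if not lesion_spectra or not healthy_spectra:
        raise ValueError("need at least one spectrum per site")

    healthy_coeffs = pd.DataFrame([_coefficients(s) for s in healthy_spectra])
    healthy_mean = healthy_coeffs.mean(axis=0)
    for name, value in healthy_mean.items():
        if abs(value) <= zero_mean_epsilon:
            raise ZeroHealthyCoefficientError(
                f"healthy-skin mean of coefficient {name!r} is "
                f"{value!r}; cannot normalize"
            )

    healthy_ref = mean_spectrum(healthy_spectra)
    rows = []
    for s in lesion_spectra:
        c = _coefficients(s)
        row = {name: c[name] / healthy_mean[name] for name in c}
        row["Rt"] = malignancy_coefficient(s, healthy_ref)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DRS_FEATURES))


# ---------------------------------------------------------------------------
# File-based interface


def read_spectrum_csv(path: str | Path, site: str = "lesion") -> ReflectanceSpectrum:
    """Read a two-column ``wavelength_nm,reflectance`` CSV."""
    df = pd.read_csv(path)
    return ReflectanceSpectrum(
        df["wavelength_nm"].to_numpy(), df["reflectance"].to_numpy(), site=site
    )


def extract_drs_from_manifest(manifest_csv: str | Path) -> pd.DataFrame:
    """Run DRS extraction over a ``tumor_id,site,path`` manifest.

    Paths are resolved relative to the manifest's directory.  Returns a
    feature table with ``tumor_id, obs_idx`` plus the six DRS columns; rows
    are ordered by tumor and lesion-spectrum order of appearance.
    """
    manifest_csv = Path(manifest_csv)
    manifest = pd.read_csv(manifest_csv)
    base = manifest_csv.parent
    out = []
    for tumor_id, grp in manifest.groupby("tumor_id", sort=True):
        lesions = [
            read_spectrum_csv(base / p, site="lesion")
            for p in grp.loc[grp["site"] == "lesion", "path"]
        ]
        healthy = [
            read_spectrum_csv(base / p, site="healthy")
            for p in grp.loc[grp["site"] == "healthy", "path"]
        ]
        feats = extract_drs_features(lesions, healthy)
        feats.insert(0, "tumor_id", tumor_id)
        feats.insert(1, "obs_idx", np.arange(len(feats)))
        out.append(feats)
    return pd.concat(out, ignore_index=True)
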