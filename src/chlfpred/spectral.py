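"""Reflectance band-ratio indices used as covariates in the Fq'/Fm' models.

MTCI (red-edge chlorophyll), PRI (xanthophyll-cycle state) and NDVI (canopy
greenness) are computed from narrow reflectance bands extracted from a full
spectrum (mean over a +/- 2 nm window, roughly eight spectrometer samples at
0.46 nm resolution) or taken directly from pre-extracted band columns in a
record table.

Two MTCI denominators are in circulation: the form implemented here by
default, (R754 - R710) / (R710 + R680), and the classic literature form with
a subtracted denominator, (R754 - R710) / (R710 - R680).  The ``variant``
argument switches between them; the additive form is the default because it
is the form the downstream models were built around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSample",
    "UndefinedIndexError",
    "SpectralCoverageError",
    "read_spectrum",
    "band_value",
    "mtci",
    "pri",
    "ndvi",
    "broadband_reflectance",
    "mtci_from_bands",
    "bands_to_indices",
]

_EPS = 1e-12


class UndefinedIndexError(ValueError):
    """Raised when an index denominator is (numerically) zero."""


class SpectralCoverageError(ValueError):
    """Raised when a spectrum does not cover a required band."""


@dataclass
class SpectrumSample:
    """A single reflectance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray  # nm
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise SpectralCoverageError("wavelengths and values must be 1-D and equal length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectralCoverageError("wavelengths must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise SpectralCoverageError("reflectance values must be finite")


def read_spectrum(path) -> SpectrumSample:
    """Read a two-column (wavelength_nm, reflectance) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectralCoverageError(f"{path}: expected (wavelength, reflectance) columns")
    return SpectrumSample(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def band_value(spectrum: SpectrumSample, center: float, window: float = 2.0) -> float:
    """Mean reflectance of the samples within ``center`` +/- ``window`` nm."""
    sel = np.abs(spectrum.wavelengths - center) <= window
    if not sel.any():
        raise SpectralCoverageError(f"spectrum does not cover {center} +/- {window} nm")
    return float(spectrum.values[sel].mean())


def mtci_from_bands(r754: float, r710: float, r680: float, variant: str = "as_published") -> float:
    """Chlorophyll index from the three red-edge bands; see module docstring."""
    if variant == "as_published":
        denom = r710 + r680
    elif variant == "literature":
        denom = r710 - r680
    else:
        raise ValueError(f"unknown MTCI variant '{variant}'")
    if abs(denom) < _EPS:
        raise UndefinedIndexError("MTCI denominator is zero")
    return (r754 - r710) / denom


def mtci(spectrum: SpectrumSample, variant: str = "as_published", window: float = 2.0) -> float:
    return mtci_from_bands(
        band_value(spectrum, 754, window),
        band_value(spectrum, 710, window),
        band_value(spectrum, 680, window),
        variant,
    )


def pri(spectrum: SpectrumSample, window: float = 2.0) -> float:
    """Photochemical reflectance index (R531 - R570) / (R531 + R570)."""
    r531 = band_value(spectrum, 531, window)
    r570 = band_value(spectrum, 570, window)
    denom = r531 + r570
    if abs(denom) < _EPS:
        raise UndefinedIndexError("PRI denominator is zero")
    return (r531 - r570) / denom


def ndvi(spectrum: SpectrumSample, window: float = 2.0) -> float:
    """Normalized difference vegetation index (R800 - R680) / (R800 + R680)."""
    r800 = band_value(spectrum, 800, window)
    r680 = band_value(spectrum, 680, window)
    denom = r800 + r680
    if abs(denom) < _EPS:
        raise UndefinedIndexError("NDVI denominator is zero")
    return (r800 - r680) / denom


def broadband_reflectance(spectrum: SpectrumSample, lo: float = 400.0, hi: float = 800.0) -> float:
    """Mean reflectance over [lo, hi] nm.

    Serves as the canopy light-heterogeneity covariate; the exact definition
    of that covariate is an interpretation (a configurable broadband mean),
    not a published formula.
    """
    sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not sel.any():
        raise SpectralCoverageError(f"spectrum does not cover [{lo}, {hi}] nm")
    return float(spectrum.values[sel].mean())


def bands_to_indices(records: pd.DataFrame, variant: str = "as_published") -> pd.DataFrame:
    """Attach index columns computed from pre-extracted band columns.

    Adds ``mtci`` when r754/r710/r680 are present, ``pri`` for r531/r570,
    ``ndvi`` for r800/r680, and ``reflectance`` as the mean over whatever
    band columns exist.  Rows where a denominator vanishes get NaN rather
    than raising, since record tables are filtered downstream.
    """
    out = records.copy()
    band_cols = [c for c in ("r531", "r570", "r680", "r710", "r754", "r800") if c in out.columns]
    if {"r754", "r710", "r680"} <= set(band_cols):
        if variant == "as_published":
            denom = out["r710"] + out["r680"]
        elif variant == "literature":
            denom = out["r710"] - out["r680"]
        else:
            raise ValueError(f"unknown MTCI variant '{variant}'")
        out["mtci"] = np.where(np.abs(denom) < _EPS, np.nan, (out["r754"] - out["r710"]) / denom)
    if {"r531", "r570"} <= set(band_cols):
        denom = out["r531"] + out["r570"]
        out["pri"] = np.where(np.abs(denom) < _EPS, np.nan, (out["r531"] - out["r570"]) / denom)
    if {"r800", "r680"} <= set(band_cols):
        denom = out["r800"] + out["r680"]
        out["ndvi"] = np.where(np.abs(denom) < _EPS, np.nan, (out["r800"] - out["r680"]) / denom)
    if band_cols:
        out["reflectance"] = out[band_cols].mean(axis=1)
    return out
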