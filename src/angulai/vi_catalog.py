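"""Catalog of published narrowband vegetation indices for LAI estimation.

Each index is a closed-form combination of reflectances at fixed
wavelengths (nearest-band rule on the analysis grid).  Formulas follow the
forms conventionally tabulated for hyperspectral LAI work; the symbolic
NIR / red-edge / red bands of CIred-edge and MTCI are fixed at 790 / 720 /
670 nm, and the broad MSAVI2 bands are read as region means over
760-900 nm and 630-690 nm.

Undefined values (zero denominators, negative square-root arguments in the
MCARI2/MTVI2/MSAVI2 family) are returned as NaN markers, never raised;
downstream regressions drop flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .spectra_io import AngularSpectraSet, band_at

__all__ = ["VIDefinition", "list_catalog", "catalog_names", "compute_vi", "compute_vi_matrix"]

# symbolic band conventions, exposed for configuration
NIR_NM = 790.0
RED_EDGE_NM = 720.0
RED_NM = 670.0


class _Bands:
    """Band accessor bound to one spectra set."""

    def __init__(self, spectra: AngularSpectraSet):
        self._spectra = spectra

    def R(self, wavelength: float) -> np.ndarray:
        return band_at(self._spectra, wavelength)

    def Rmean(self, lo: float, hi: float) -> np.ndarray:
        wl = self._spectra.grid.wavelengths
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise ValueError(f"no bands in region {lo:g}-{hi:g} nm")
        return self._spectra.reflectance[:, mask].mean(axis=1)


@dataclass(frozen=True)
class VIDefinition:
    name: str
    n_bands: int  # 2 | 3 | 4 class label
    required_wavelengths: tuple[float, ...]
    formula: Callable[[_Bands], np.ndarray]
    description: str = ""


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def _safe_sqrt(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.where(x < 0, np.nan, np.sqrt(np.maximum(x, 0.0)))


def _ndvi(b):
    return _safe_div(b.R(810) - b.R(680), b.R(810) + b.R(680))


def _rvi(b):
    return _safe_div(b.R(810), b.R(680))


def _dvi(b):
    return b.R(810) - b.R(680)


def _osavi(b):
    return 1.16 * _safe_div(b.R(800) - b.R(670), b.R(800) + b.R(670) + 0.16)


def _pri(b):
    return _safe_div(b.R(570) - b.R(531), b.R(570) + b.R(531))


def _wdrvi(b):
    # trailing offset term kept verbatim: (1 - 0.2) / (1 + 0.2)
    return _safe_div(0.2 * b.R(800) - b.R(670), 0.2 * b.R(800) + b.R(670)) + 0.8 / 1.2


def _vog(b):
    return _safe_div(b.R(740), b.R(720))


def _ci_red_edge(b):
    return _safe_div(b.R(NIR_NM), b.R(RED_EDGE_NM)) - 1.0


def _mnd705(b):
    return _safe_div(b.R(750) - b.R(705), b.R(750) + b.R(705) - 2 * b.R(445))


def _msr705(b):
    return _safe_div(b.R(750) - b.R(445), b.R(705) - b.R(445))


def _evi1(b):
    return 2.5 * _safe_div(b.R(860) - b.R(645), 1 + b.R(860) + 6 * b.R(645) - 7.5 * b.R(470))


def _mcari2(b):
    num = 1.5 * (2.5 * (b.R(800) - b.R(670)) - 1.3 * (b.R(800) - b.R(550)))
    den = _safe_sqrt((2 * b.R(800) + 1) ** 2 - 6 * b.R(800) + 5 * _safe_sqrt(b.R(670))) - 0.5
    return _safe_div(num, den)


def _mtvi2(b):
    num = 1.5 * (1.2 * (b.R(800) - b.R(550)) - 2.5 * (b.R(670) - b.R(550)))
    den = _safe_sqrt((2 * b.R(800) + 1) ** 2 - (6 * b.R(800) - 5 * _safe_sqrt(b.R(670))) - 0.5)
    return _safe_div(num, den)


def _sipi(b):
    return _safe_div(b.R(800) - b.R(445), b.R(800) - b.R(680))


def _mtci(b):
    return _safe_div(b.R(NIR_NM) - b.R(RED_EDGE_NM), b.R(RED_EDGE_NM) - b.R(RED_NM))


def _ddn(b):
    return 2 * b.R(710) - b.R(660) - b.R(760)


def _tcari_osavi(b):
    tcari = 3 * ((b.R(700) - b.R(670)) - 0.2 * (b.R(700) - b.R(550)) * _safe_div(b.R(700), b.R(670)))
    return _safe_div(tcari, _osavi(b))


def _msavi2(b):
    nir = b.Rmean(760, 900)
    red = b.Rmean(630, 690)
    return 0.5 * (2 * nir + 1 - _safe_sqrt((2 * nir + 1) ** 2 - 8 * (nir - red)))


def _rep(b):
    # linear-interpolation red-edge position: 700 is the anchor wavelength (nm)
    return 700.0 + 40 * _safe_div((b.R(670) + b.R(780)) / 2 - b.R(700), b.R(740) - b.R(700))


def _dd(b):
    return (b.R(749) - b.R(720)) - (b.R(701) - b.R(672))


def _vog2(b):
    return _safe_div(b.R(734) - b.R(747), b.R(715) + b.R(726))


_CATALOG: tuple[VIDefinition, ...] = (
    VIDefinition("NDVI", 2, (810, 680), _ndvi, "Normalized Difference Vegetation Index"),
    VIDefinition("RVI", 2, (810, 680), _rvi, "Ratio Vegetation Index"),
    VIDefinition("DVI", 2, (810, 680), _dvi, "Difference Vegetation Index"),
    VIDefinition("OSAVI", 2, (800, 670), _osavi, "Optimized Soil Adjusted Vegetation Index"),
    VIDefinition("PRI", 2, (570, 531), _pri, "Photochemical Reflectance Index"),
    VIDefinition("WDRVI", 2, (800, 670), _wdrvi, "Wide Dynamic Range Vegetation Index"),
    VIDefinition("VOG", 2, (740, 720), _vog, "Vogelmann Index"),
    VIDefinition("CIred-edge", 2, (NIR_NM, RED_EDGE_NM), _ci_red_edge, "Red-edge Chlorophyll Index"),
    VIDefinition("mND705", 3, (750, 705, 445), _mnd705, "Modified Red-edge NDVI"),
    VIDefinition("mSR705", 3, (750, 705, 445), _msr705, "Modified Red-edge Simple Ratio"),
    VIDefinition("EVI-1", 3, (860, 645, 470), _evi1, "Enhanced Vegetation Index"),
    VIDefinition("MCARI2", 3, (800, 670, 550), _mcari2, "Modified Chlorophyll Absorption Index 2"),
    VIDefinition("MTVI2", 3, (800, 670, 550), _mtvi2, "Modified Triangular Vegetation Index 2"),
    VIDefinition("SIPI", 3, (800, 445, 680), _sipi, "Structure Insensitive Pigment Index"),
    VIDefinition("MTCI", 3, (NIR_NM, RED_EDGE_NM, RED_NM), _mtci, "MERIS Terrestrial Chlorophyll Index"),
    VIDefinition("DDn", 3, (710, 660, 760), _ddn, "New Double Difference Index"),
    VIDefinition("TCARI/OSAVI", 4, (700, 670, 550, 800), _tcari_osavi, "TCARI over OSAVI ratio"),
    VIDefinition("MSAVI2", 4, (760, 900, 630, 690), _msavi2, "Modified Soil-Adjusted Vegetation Index (region means)"),
    VIDefinition("REP", 4, (700, 670, 780, 740), _rep, "Red-edge Position (linear interpolation)"),
    VIDefinition("DD", 4, (749, 720, 701, 672), _dd, "Double Difference Index"),
    VIDefinition("VOG-2", 4, (734, 747, 715, 726), _vog2, "Vogelmann Index 2"),
)


def list_catalog() -> list[VIDefinition]:
    """All published indices in the catalog, grouped 2- / 3- / 4-band."""
    return list(_CATALOG)


def catalog_names() -> list[str]:
    return [d.name for d in _CATALOG]


def compute_vi(name: str, spectra: AngularSpectraSet) -> np.ndarray:
    """Per-sample values of the named index; undefined samples are NaN."""
    for d in _CATALOG:
        if d.name == name:
            return np.asarray(d.formula(_Bands(spectra)), dtype=float)
    raise KeyError(f"unknown vegetation index {name!r}; known: {catalog_names()}")


def compute_vi_matrix(names: list[str], spectra: AngularSpectraSet) -> np.ndarray:
    """Samples x indices matrix, column order following ``names``."""
    if not names:
        return np.empty((spectra.n_samples, 0))
    return np.column_stack([compute_vi(n, spectra) for n in names])
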