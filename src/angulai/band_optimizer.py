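"""Exhaustive two-band index optimization against LAI.

For each ordered wavelength pair (lambda1, lambda2) on a search grid, the
index value (normalized difference, simple ratio, or difference form) is
computed per sample and regressed linearly against LAI; the coefficient of
determination of that fit fills an R2 surface over the pair grid, whose
argmax gives the optimal band pair per view zenith angle.

The surface is vectorized through the identity R2 = corr(index, LAI)^2 for
a single-predictor least-squares fit, but is numerically equal to a naive
per-cell regression loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Dataset, WavelengthGrid

__all__ = [
    "INDEX_TYPES",
    "R2Surface",
    "OptimalPair",
    "index_value",
    "r2_surface",
    "select_optimum",
    "export_surface",
    "read_surface",
]

INDEX_TYPES = ("ND", "SR", "DVI")


@dataclass
class R2Surface:
    """R2 of LAI-vs-index linear fits over all band pairs, one index type/VZA."""

    index_type: str
    vza: float
    grid: WavelengthGrid
    r2: np.ndarray  # (bands x bands), NaN = undefined cell
    n_used: int

    def __post_init__(self):
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"index_type must be one of {INDEX_TYPES}")
        if self.r2.shape != (len(self.grid), len(self.grid)):
            raise ValueError("r2 matrix must be square over the search grid")


@dataclass
class OptimalPair:
    index_type: str
    vza: float
    lambda1: float
    lambda2: float
    r2: float
    slope: float
    intercept: float


def index_value(index_type: str, r1, r2):
    """Two-band index value; zero denominators yield NaN markers.

    ND = (r1 - r2) / (r1 + r2);  SR = r1 / r2;  DVI = r1 - r2.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if index_type == "ND":
        den = r1 + r2
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (r1 - r2) / den
        return np.where(den == 0, np.nan, v)
    if index_type == "SR":
        with np.errstate(divide="ignore", invalid="ignore"):
            v = r1 / r2
        return np.where(r2 == 0, np.nan, v)
    if index_type == "DVI":
        return r1 - r2
    raise ValueError(f"unknown index type {index_type!r}; expected one of {INDEX_TYPES}")


def _fit_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R2 of OLS y = a*x + b; NaN if x constant, 0 if y constant."""
    valid = np.isfinite(x)
    if valid.sum() < 3:
        return np.nan
    x, y = x[valid], y[valid]
    sx = x.std()
    if sx == 0:
        return np.nan
    sy = y.std()
    if sy == 0:
        return 0.0
    c = np.corrcoef(x, y)[0, 1]
    return float(c * c)


def r2_surface(dataset: Dataset, index_type: str, step: float = 1.0) -> R2Surface:
    """R2 surface over all ordered band pairs at the given search step (nm).

    Fits use the samples of ``dataset`` (pass the calibration subset for a
    calibration-set search).  Cells with a constant index (the ND/DVI
    diagonal, the constant-SR diagonal) or fewer than 3 valid samples are
    NaN.  A constant-LAI dataset yields R2 = 0 everywhere defined.
    """
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples to fit")
    wl = dataset.spectra.grid.wavelengths
    sel = np.isclose((wl - wl[0]) % step, 0) | np.isclose((wl - wl[0]) % step, step)
    idx = np.nonzero(sel)[0]
    sub_wl = wl[idx]
    X = dataset.spectra.reflectance[:, idx]
    y = dataset.lai.astype(float)
    n, B = X.shape

    yc = y - y.mean()
    sy = y.std()
    if sy == 0:
        warnings.warn("degenerate LAI (zero variance); all R2 defined as 0")

    r2 = np.full((B, B), np.nan)
    has_nonpos = bool((X <= 0).any())
    for i in range(B):
        r1 = X[:, i][:, None]  # (n, 1)
        vals = index_value(index_type, np.broadcast_to(r1, (n, B)), X)
        if has_nonpos or not np.isfinite(vals).all():
            # slow path: per-cell NaN handling
            for j in range(B):
                r2[i, j] = _fit_r2(vals[:, j], y)
            continue
        vc = vals - vals.mean(axis=0)
        sv = vals.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (vc * yc[:, None]).mean(axis=0) / (sv * sy)
        row = c * c
        row[sv == 0] = np.nan
        if sy == 0:
            row = np.where(sv == 0, np.nan, 0.0)
        r2[i] = row
    return R2Surface(
        index_type=index_type,
        vza=dataset.spectra.vza,
        grid=WavelengthGrid(sub_wl),
        r2=r2,
        n_used=n,
    )


def select_optimum(surface: R2Surface, dataset: Dataset | None = None) -> OptimalPair:
    """Argmax cell of the surface; ties go to smallest lambda1 then lambda2.

    If ``dataset`` is given, the linear LAI model is refit at the winning
    pair to report slope and intercept; otherwise they are NaN.
    """
    if not np.isfinite(surface.r2).any():
        raise ValueError("surface has no defined cells")
    best = np.nanmax(surface.r2)
    cells = np.argwhere(surface.r2 == best)
    i, j = min(map(tuple, cells))  # lexicographic: smallest lambda1, then lambda2
    wl = surface.grid.wavelengths
    lam1, lam2 = float(wl[i]), float(wl[j])
    slope = intercept = float("nan")
    if dataset is not None:
        from .spectra_io import band_at

        v = index_value(surface.index_type, band_at(dataset.spectra, lam1),
                        band_at(dataset.spectra, lam2))
        ok = np.isfinite(v)
        slope, intercept = np.polyfit(v[ok], dataset.lai[ok], 1)
    return OptimalPair(
        index_type=surface.index_type,
        vza=surface.vza,
        lambda1=lam1,
        lambda2=lam2,
        r2=float(best),
        slope=float(slope),
        intercept=float(intercept),
    )


def export_surface(surface: R2Surface, path) -> None:
    """Long-format CSV (lambda1, lambda2, r2); missing cells omitted."""
    wl = surface.grid.wavelengths
    ii, jj = np.nonzero(np.isfinite(surface.r2))
    pd.DataFrame(
        {"lambda1": wl[ii], "lambda2": wl[jj], "r2": surface.r2[ii, jj]}
    ).to_csv(path, index=False, float_format="%.12g")


def read_surface(path, index_type: str = "ND", vza: float = 0.0, n_used: int = 0) -> R2Surface:
    """Rebuild a surface matrix from an exported long-format CSV."""
    df = pd.read_csv(path)
    wl = np.unique(np.concatenate([df["lambda1"].values, df["lambda2"].values]))
    grid = WavelengthGrid(wl)
    pos = {w: i for i, w in enumerate(wl)}
    r2 = np.full((wl.size, wl.size), np.nan)
    for lam1, lam2, v in df.itertuples(index=False):
        r2[pos[lam1], pos[lam2]] = v
    return R2Surface(index_type=index_type, vza=vza, grid=grid, r2=r2, n_used=n_used)
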