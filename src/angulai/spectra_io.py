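"""Data model and I/O for multi-angular hyperspectral LAI datasets.

The core containers are :class:`AngularSpectraSet` (a samples x bands
reflectance matrix tagged with one signed view zenith angle) and
:class:`Dataset` (spectra aligned with per-sample LAI).  All analysis
runs on the canonical 400-900 nm, 1-nm wavelength grid (501 bands);
instrument-resolution spectra are linearly interpolated onto it.

CSV dialect: spectra files have a header ``sample_id,400,401,...,900``;
LAI files have a header ``sample_id,lai``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "AngularSpectraSet",
    "Dataset",
    "Partition",
    "SpectraError",
    "AlignmentError",
    "MissingBandError",
    "canonical_grid",
    "read_dataset",
    "write_dataset",
    "resample_to_grid",
    "band_at",
    "make_partition",
]

#: signed view zenith angles used throughout (degrees, negative = backscatter)
VZA_SEQUENCE = tuple(range(-60, 61, 10))

GRID_MIN_NM = 325.0
GRID_MAX_NM = 1075.0


class SpectraError(ValueError):
    """Base error for data-model violations."""


class AlignmentError(SpectraError):
    """Sample identifiers do not match between spectra and LAI tables."""


class MissingBandError(SpectraError):
    """Requested wavelength has no grid band within tolerance."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers in nm, within [325, 1075]."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if wl[0] < GRID_MIN_NM or wl[-1] > GRID_MAX_NM:
            raise SpectraError(
                f"wavelengths must lie within [{GRID_MIN_NM:g}, {GRID_MAX_NM:g}] nm"
            )
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def nearest_index(self, wavelength: float, tol_nm: float = 2.0) -> int:
        """Index of the band nearest ``wavelength``; error beyond ``tol_nm``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol_nm:
            raise MissingBandError(
                f"no band within {tol_nm:g} nm of {wavelength:g} nm "
                f"(grid spans {self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm)"
            )
        return i


def canonical_grid() -> WavelengthGrid:
    """The 400-900 nm, 1-nm analysis grid (501 bands)."""
    return WavelengthGrid(np.arange(400.0, 901.0, 1.0))


@dataclass
class AngularSpectraSet:
    """Reflectance matrix (samples x bands) for one view zenith angle."""

    vza: float
    grid: WavelengthGrid
    reflectance: np.ndarray
    sample_ids: list[str]

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 2:
            raise SpectraError("reflectance must be a 2-D matrix")
        if r.shape[0] != len(self.sample_ids):
            raise SpectraError(
                f"{r.shape[0]} reflectance rows vs {len(self.sample_ids)} sample ids"
            )
        if r.shape[1] != len(self.grid):
            raise SpectraError(
                f"{r.shape[1]} reflectance columns vs {len(self.grid)} grid bands"
            )
        if np.any(~np.isfinite(r)) or r.min() < 0.0 or r.max() > 1.0:
            raise SpectraError("reflectance values must be finite and in [0, 1]")
        self.reflectance = r
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]


@dataclass
class Dataset:
    """An AngularSpectraSet aligned with per-sample LAI (m2 leaf / m2 ground)."""

    spectra: AngularSpectraSet
    lai: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.lai, dtype=float)
        if y.ndim != 1 or y.size != self.spectra.n_samples:
            raise SpectraError("lai length must equal sample count")
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise SpectraError("all LAI values must be finite and > 0")
        self.lai = y

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    def subset(self, ids: list[str]) -> "Dataset":
        """Rows restricted to ``ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing[:5]}")
        idx = np.array([pos[s] for s in ids], dtype=int)
        sub = AngularSpectraSet(
            vza=self.spectra.vza,
            grid=self.spectra.grid,
            reflectance=self.spectra.reflectance[idx],
            sample_ids=list(ids),
        )
        return Dataset(spectra=sub, lai=self.lai[idx])


@dataclass
class Partition:
    """Train/test split plus a k-fold assignment of the training set.

    One partition is shared across all view zenith angles because the
    physical samples are common to every angle; re-splitting per angle
    would conflate sampling noise with angular effects.
    """

    train_ids: list[str]
    test_ids: list[str]
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise SpectraError(f"train/test overlap: {sorted(overlap)[:5]}")
        if self.fold_assignment:
            bad = set(self.fold_assignment) - set(self.train_ids)
            if bad:
                raise SpectraError(f"folds assigned to non-training ids: {sorted(bad)[:5]}")

    @property
    def n_folds(self) -> int:
        return max(self.fold_assignment.values()) if self.fold_assignment else 0

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s in self.train_ids if self.fold_assignment[s] == fold]


def read_dataset(spectra_path, lai_path) -> Dataset:
    """Read a spectra CSV and a LAI CSV and align them by sample_id.

    Row order follows the LAI file.  A sample present in one file but not
    the other raises :class:`AlignmentError` naming the offending id.
    """
    spec = pd.read_csv(spectra_path, dtype={"sample_id": str})
    lai = pd.read_csv(lai_path, dtype={"sample_id": str})
    for df, path, cols in ((spec, spectra_path, None), (lai, lai_path, ("sample_id", "lai"))):
        if "sample_id" not in df.columns:
            raise SpectraError(f"{path}: missing 'sample_id' column")
    if "lai" not in lai.columns:
        raise SpectraError(f"{lai_path}: missing 'lai' column")

    try:
        wavelengths = np.array([float(c) for c in spec.columns if c != "sample_id"])
    except ValueError as e:
        raise SpectraError(f"{spectra_path}: non-numeric wavelength header ({e})") from e
    vza = _vza_from_attr_or_name(spectra_path)

    spec_ids = list(spec["sample_id"])
    lai_ids = list(lai["sample_id"])
    extra_spec = sorted(set(spec_ids) - set(lai_ids))
    extra_lai = sorted(set(lai_ids) - set(spec_ids))
    if extra_spec or extra_lai:
        raise AlignmentError(
            f"unmatched sample ids: spectra-only={extra_spec[:5]}, lai-only={extra_lai[:5]}"
        )

    raw = spec.drop(columns="sample_id").apply(pd.to_numeric, errors="coerce")
    values = raw.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise SpectraError(
            f"{spectra_path}: non-numeric reflectance at row {spec_ids[r]}, "
            f"column {wavelengths[c]:g}"
        )
    order = [spec_ids.index(s) for s in lai_ids]
    spectra = AngularSpectraSet(
        vza=vza,
        grid=WavelengthGrid(wavelengths),
        reflectance=values[order],
        sample_ids=lai_ids,
    )
    return Dataset(spectra=spectra, lai=lai["lai"].to_numpy(dtype=float))


def _vza_from_attr_or_name(path) -> float:
    """Parse a vza tag like 'spectra_vza-60' or 'spectra_vza+10' from the filename."""
    import re

    m = re.search(r"vza([+-]?\d+)", str(path))
    return float(m.group(1)) if m else 0.0


def write_dataset(dataset: Dataset, spectra_path, lai_path) -> None:
    """Write the spectra and LAI CSVs in the package dialect."""
    grid = dataset.spectra.grid.wavelengths
    cols = ["sample_id"] + [f"{w:g}" for w in grid]
    df = pd.DataFrame(dataset.spectra.reflectance, columns=cols[1:])
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(spectra_path, index=False, float_format="%.10g")
    pd.DataFrame({"sample_id": dataset.sample_ids, "lai": dataset.lai}).to_csv(
        lai_path, index=False, float_format="%.10g"
    )


def resample_to_grid(spectra: AngularSpectraSet, target: WavelengthGrid) -> AngularSpectraSet:
    """Piecewise-linear interpolation of each sample onto ``target``.

    The target range must lie within the source range; no extrapolation.
    """
    src = spectra.grid.wavelengths
    tgt = target.wavelengths
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise SpectraError(
            f"target grid [{tgt[0]:g}, {tgt[-1]:g}] extends beyond source "
            f"[{src[0]:g}, {src[-1]:g}]; extrapolation is not supported"
        )
    out = np.empty((spectra.n_samples, tgt.size))
    for i in range(spectra.n_samples):
        out[i] = np.interp(tgt, src, spectra.reflectance[i])
    return AngularSpectraSet(
        vza=spectra.vza, grid=target, reflectance=out, sample_ids=list(spectra.sample_ids)
    )


def band_at(spectra: AngularSpectraSet, wavelength: float) -> np.ndarray:
    """Per-sample reflectance at the grid band nearest ``wavelength``.

    Nearest-band rule (no interpolation); exact on the canonical 1-nm grid.
    """
    return spectra.reflectance[:, spectra.grid.nearest_index(wavelength)]


def make_partition(dataset: Dataset, n_train: int = 176, k: int = 5, seed: int = 0) -> Partition:
    """Uniform random train/test split plus k-fold assignment of the training set.

    Deterministic given ``seed``.  The same partition is reused across all
    view zenith angles.
    """
    n = dataset.n_samples
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = dataset.sample_ids
    train_ids = [ids[i] for i in sorted(perm[:n_train])]
    test_ids = [ids[i] for i in sorted(perm[n_train:])]
    # near-equal folds: first (n_train % k) folds get one extra sample
    fold_perm = rng.permutation(n_train)
    folds = np.empty(n_train, dtype=int)
    sizes = [n_train // k + (1 if f < n_train % k else 0) for f in range(k)]
    start = 0
    for f, size in enumerate(sizes, start=1):
        folds[fold_perm[start : start + size]] = f
        start += size
    assignment = {train_ids[i]: int(folds[i]) for i in range(n_train)}
    return Partition(train_ids=train_ids, test_ids=test_ids, fold_assignment=assignment)
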