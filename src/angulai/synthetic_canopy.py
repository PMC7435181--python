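"""Synthetic multi-angular canopy reflectance generator.

Emulates the statistical structure of a multi-angular winter-wheat
spectroscopy campaign: 221 canopy samples with LAI drawn from a truncated
normal (mean 4.90, SD 1.63, range 1.25-8.76), observed at 13 view zenith
angles from -60 deg (backscatter) to +60 deg (forward scatter) in 10-deg
steps on the 400-900 nm grid.

The canopy model is a two-stream linear mixture: the sensor sees leaf
reflectance where the canopy covers the view line and soil where it does
not, with the visible-soil fraction given by a Beer-Lambert gap fraction
exp(-k * Omega * LAI / cos(vza)).  Leaf optics are a parametric green-leaf
spectrum: a NIR plateau, Gaussian chlorophyll absorption troughs in the
blue (~450 nm) and red (~670 nm) whose depth saturates with chlorophyll
content, a green reflectance peak (~550 nm), and a sigmoid red edge whose
inflection shifts to longer wavelengths with chlorophyll.  Chlorophyll is
coupled to LAI so red-edge bands carry the LAI signal.

Observation noise has three components, each with SD growing linearly in
|vza|: a spectrally smooth multiplicative field (Gaussian-correlated over
~35 nm, emulating BRDF and illumination drift, which nearby bands share
and distant band pairs do not), an independent per-band multiplicative
term, and an additive noise floor that dominates in dark absorption
bands.  The angular noise growth (together with stronger gap saturation
at oblique view) degrades estimation quality away from nadir.

This is a statistical stand-in, not a radiative transfer model: no hotspot
kernel, no leaf angle distribution, no SWIR.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .spectra_io import (
    VZA_SEQUENCE,
    AngularSpectraSet,
    Dataset,
    WavelengthGrid,
    canonical_grid,
)

__all__ = [
    "CanopyConfig",
    "LeafSpectrumParams",
    "sample_lai",
    "leaf_reflectance",
    "gap_fraction",
    "soil_spectrum",
    "simulate_canopy",
    "generate_dataset",
    "default_config",
]

_DEFAULT_CONFIG_FILE = Path(__file__).with_name("default_config.yaml")


@dataclass(frozen=True)
class LeafSpectrumParams:
    """Parametric green-leaf reflectance spectrum.

    All levels are reflectances in [0, 1]; centers/widths in nm;
    chlorophyll (cab) in ug cm-2.
    """

    nir_plateau: float = 0.50
    vis_base: float = 0.08
    blue_center: float = 450.0
    blue_width: float = 30.0
    blue_max_depth: float = 0.055
    red_center: float = 670.0
    red_width: float = 25.0
    red_max_depth: float = 0.065
    green_center: float = 550.0
    green_width: float = 25.0
    green_peak: float = 0.06
    red_edge_center: float = 705.0
    red_edge_width: float = 12.0
    red_edge_shift_per_cab: float = 0.5
    cab_saturation: float = 8.0


@dataclass(frozen=True)
class CanopyConfig:
    """All simulator parameters; defaults ship in default_config.yaml."""

    n_samples: int = 221
    # truncated-normal LAI distribution (m2 m-2)
    lai_mean: float = 4.90
    lai_sd: float = 1.63
    lai_min: float = 1.25
    lai_max: float = 8.76
    # chlorophyll-LAI coupling (ug cm-2)
    cab_base: float = 15.0
    cab_per_lai: float = 5.0
    cab_sd: float = 4.0
    # canopy structure
    k_ext: float = 0.5
    clumping: float = 0.9
    # soil line: reflectance = intercept + slope * (lambda - 400), times brightness
    soil_intercept: float = 0.10
    soil_slope: float = 0.00028
    soil_brightness_sd: float = 0.08
    # back/forward asymmetry: vegetation term scaled by 1 + asym_h * vza / 60;
    # negative asym_h makes backscatter (negative vza) brighter
    asym_h: float = -0.05
    # noise SDs at nadir; each scales with (1 + noise_gamma * |vza| / 60)
    noise_sd0: float = 0.01         # independent multiplicative, per band
    noise_smooth_sd0: float = 0.045  # spectrally smooth multiplicative
    noise_corr_nm: float = 35.0      # Gaussian correlation length of the smooth field
    noise_add_sd0: float = 0.004     # additive floor (reflectance units)
    noise_gamma: float = 2.0
    seed: int = 0
    leaf: LeafSpectrumParams = dataclasses.field(default_factory=LeafSpectrumParams)

    def __post_init__(self):
        if self.lai_min <= 0 or self.lai_min >= self.lai_max:
            raise ValueError("require 0 < lai_min < lai_max")
        if self.k_ext <= 0:
            raise ValueError("k_ext must be > 0")
        if not 0 < self.clumping <= 1:
            raise ValueError("clumping must be in (0, 1]")
        if min(self.noise_sd0, self.noise_smooth_sd0, self.noise_add_sd0,
               self.noise_gamma) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.noise_corr_nm <= 0:
            raise ValueError("noise_corr_nm must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "CanopyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        leaf = LeafSpectrumParams(**raw.pop("leaf", {}))
        return cls(leaf=leaf, **raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def replace(self, **kw) -> "CanopyConfig":
        return dataclasses.replace(self, **kw)


def default_config() -> CanopyConfig:
    """The versioned default configuration shipped with the package."""
    if _DEFAULT_CONFIG_FILE.exists():
        return CanopyConfig.from_yaml(_DEFAULT_CONFIG_FILE)
    return CanopyConfig()


def sample_lai(config: CanopyConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-sample LAI from the truncated normal the campaign reports."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.lai_sd == 0:
        return np.full(config.n_samples, config.lai_mean)
    a = (config.lai_min - config.lai_mean) / config.lai_sd
    b = (config.lai_max - config.lai_mean) / config.lai_sd
    return stats.truncnorm.rvs(
        a, b, loc=config.lai_mean, scale=config.lai_sd, size=config.n_samples,
        random_state=rng,
    )


def leaf_reflectance(
    cab: float, params: LeafSpectrumParams, grid: WavelengthGrid
) -> np.ndarray:
    """Parametric leaf reflectance spectrum for chlorophyll content ``cab``.

    Trough depths saturate as 1 - exp(-cab / cab_saturation); the red-edge
    inflection moves to longer wavelengths with cab.  Output clipped to
    [0.01, 0.99].
    """
    cab = max(float(cab), 0.0)
    wl = grid.wavelengths
    depth = 1.0 - np.exp(-cab / params.cab_saturation)
    edge_center = params.red_edge_center + params.red_edge_shift_per_cab * cab
    edge = 1.0 / (1.0 + np.exp(-(wl - edge_center) / params.red_edge_width))
    r = params.vis_base + (params.nir_plateau - params.vis_base) * edge
    r = r + params.green_peak * np.exp(-0.5 * ((wl - params.green_center) / params.green_width) ** 2)
    r = r - depth * params.blue_max_depth * np.exp(
        -0.5 * ((wl - params.blue_center) / params.blue_width) ** 2
    )
    r = r - depth * params.red_max_depth * np.exp(
        -0.5 * ((wl - params.red_center) / params.red_width) ** 2
    )
    return np.clip(r, 0.01, 0.99)


def gap_fraction(lai: float | np.ndarray, vza: float, config: CanopyConfig) -> float | np.ndarray:
    """Beer-Lambert fraction of soil background visible along the view line."""
    if abs(vza) >= 90:
        raise ValueError(f"|vza| must be < 90 deg, got {vza}")
    path = 1.0 / np.cos(np.deg2rad(vza))
    return np.exp(-config.k_ext * config.clumping * np.asarray(lai, dtype=float) * path)


def soil_spectrum(grid: WavelengthGrid, config: CanopyConfig, brightness: float = 1.0) -> np.ndarray:
    """Soil-line reflectance, a gently sloped bright background."""
    wl = grid.wavelengths
    return brightness * (config.soil_intercept + config.soil_slope * (wl - 400.0))


def _smooth_field(rng: np.random.Generator, wavelengths: np.ndarray, corr_nm: float) -> np.ndarray:
    """Unit-variance Gaussian field with ~corr_nm spectral correlation."""
    step = float(np.median(np.diff(wavelengths))) if wavelengths.size > 1 else 1.0
    half = max(int(round(3 * corr_nm / step)), 1)
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / corr_nm) ** 2)
    kernel /= np.sqrt((kernel**2).sum())
    white = rng.normal(size=wavelengths.size + 2 * half)
    return np.convolve(white, kernel, mode="same")[half:-half]


def simulate_canopy(
    lai: float,
    cab: float,
    vza: float,
    config: CanopyConfig,
    grid: WavelengthGrid | None = None,
    rng: np.random.Generator | None = None,
    soil_brightness: float = 1.0,
) -> np.ndarray:
    """One canopy spectrum: angular leaf/soil mixture plus observation noise.

    R(lambda) = a(vza) * (1 - g) * leaf(lambda) + g * soil(lambda) with
    g the gap fraction and a(vza) = 1 + asym_h * vza / 60.  Observation
    noise (applied only when an rng is supplied) is multiplicative with a
    spectrally smooth and an independent per-band component, plus an
    additive floor; every SD grows by (1 + noise_gamma * |vza| / 60).
    The result is clipped to [0, 1].
    """
    grid = canonical_grid() if grid is None else grid
    g = gap_fraction(lai, vza, config)
    leaf = leaf_reflectance(cab, config.leaf, grid)
    soil = soil_spectrum(grid, config, soil_brightness)
    a = 1.0 + config.asym_h * vza / 60.0
    r = a * (1.0 - g) * leaf + g * soil
    if rng is not None:
        grow = 1.0 + config.noise_gamma * abs(vza) / 60.0
        factor = np.ones_like(r)
        if config.noise_smooth_sd0 > 0:
            factor += config.noise_smooth_sd0 * grow * _smooth_field(
                rng, grid.wavelengths, config.noise_corr_nm
            )
        if config.noise_sd0 > 0:
            factor += rng.normal(0.0, config.noise_sd0 * grow, size=r.shape)
        r = r * factor
        if config.noise_add_sd0 > 0:
            r = r + rng.normal(0.0, config.noise_add_sd0 * grow, size=r.shape)
    return np.clip(r, 0.0, 1.0)


def generate_dataset(
    config: CanopyConfig, vzas: tuple[float, ...] | list[float] = VZA_SEQUENCE
) -> dict[float, Dataset]:
    """Generate one Dataset per view zenith angle, sharing samples and LAI.

    LAI, chlorophyll and soil brightness are drawn once per sample; every
    angle observes the same underlying canopy state and differs only in
    geometry and observation noise.  Bit-reproducible given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    grid = canonical_grid()
    lai = sample_lai(config, rng)
    cab = np.maximum(
        config.cab_base + config.cab_per_lai * lai + rng.normal(0, config.cab_sd, lai.size),
        0.0,
    )
    brightness = np.maximum(1.0 + rng.normal(0, config.soil_brightness_sd, lai.size), 0.2)
    ids = [f"s{i + 1:03d}" for i in range(config.n_samples)]

    datasets: dict[float, Dataset] = {}
    for vza in vzas:
        refl = np.empty((config.n_samples, len(grid)))
        for i in range(config.n_samples):
            refl[i] = simulate_canopy(
                lai[i], cab[i], vza, config, grid=grid, rng=rng,
                soil_brightness=brightness[i],
            )
        spectra = AngularSpectraSet(vza=vza, grid=grid, reflectance=refl, sample_ids=ids)
        datasets[vza] = Dataset(spectra=spectra, lai=lai.copy())
    return datasets
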