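"""Radiance-to-reflectance calibration.

Two corrections are applied to raw push-broom radiance cubes:

* **flat-field** division by a "bright image" of a uniform white PTFE
  block spanning the field of view, which removes across-field
  illumination non-uniformity (in push-broom geometry illumination varies
  across samples/columns, not lines, so the bright cube is averaged over
  its lines);
* **spectral calibration** by division with the median spectrum of an
  in-scene Spectralon reflectance standard, converting radiance ratios to
  unitless reflectance.

The nominal reflectance of the standard defaults to 1.0 (plain division
by the 99% standard); pass ``nominal=0.99`` for the physically exact
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube import HyperCube
from .spectra import ReflectanceSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "StandardRegion",
    "flat_field",
    "standard_spectrum",
    "to_reflectance",
    "calibrate_cube",
]


@dataclass
class StandardRegion:
    """Pixel mask identifying the in-scene reflectance standard."""

    mask: np.ndarray
    nominal_reflectance: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("standard-region mask is empty")
        if not (0 < self.nominal_reflectance <= 1):
            raise ValueError("nominal reflectance must be in (0, 1]")


def flat_field(cube: HyperCube, bright: HyperCube) -> HyperCube:
    """Divide each pixel spectrum by the bright reference for its column.

    The bright cube is averaged over its lines, producing one reference
    spectrum per column; zero entries in the reference are flagged as
    missing (NaN) in the output and counted in the log.
    """
    if bright.samples != cube.samples or bright.bands != cube.bands:
        raise ValueError(
            f"bright cube shape ({bright.samples} samples, {bright.bands} "
            f"bands) does not match cube ({cube.samples}, {cube.bands})"
        )
    ref = bright.data.mean(axis=0)  # (samples, bands)
    zero = ref <= 0
    n_zero = int(np.count_nonzero(zero))
    out = np.empty_like(cube.data, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(cube.data, ref[None, :, :], out=out)
    if n_zero:
        logger.warning("flat_field: %d zero reference entries set to missing",
                       n_zero)
        out[:, zero] = np.nan
    meta = dict(cube.meta)
    meta["flat_fielded"] = True
    return HyperCube(out, cube.wavelengths.copy(), cube.interleave, meta)


def standard_spectrum(cube: HyperCube, region: StandardRegion) -> ReflectanceSpectrum:
    """Per-band median spectrum over the standard's pixels."""
    if region.mask.shape != cube.data.shape[:2]:
        raise ValueError("standard mask shape does not match cube")
    pixels = cube.data[region.mask]  # (n_pixels, bands)
    if pixels.size == 0:
        raise ValueError("standard mask selects no pixels")
    med = np.nanmedian(pixels, axis=0)
    return ReflectanceSpectrum(cube.wavelengths, med,
                               flags=frozenset({"raw"}), label="standard")


def to_reflectance(sample: ReflectanceSpectrum, standard: ReflectanceSpectrum,
                   nominal: float = 1.0, flag_cap: float = 2.0) -> ReflectanceSpectrum:
    """Spectrally calibrate a sample by division with the standard spectrum.

    Values may legitimately exceed 1 (specular highlights); they are not
    clipped, but values above ``flag_cap`` are counted in the log.  Bands
    where the standard is zero become missing (NaN).
    """
    if len(sample) != len(standard) or not np.allclose(
            sample.wavelengths, standard.wavelengths):
        raise ValueError("sample and standard are on different wavelength grids")
    std = standard.values
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sample.values / std * nominal
    zero = std <= 0
    if zero.any():
        logger.warning("to_reflectance: %d zero standard bands set to missing",
                       int(zero.sum()))
        out = np.where(zero, np.nan, out)
    n_high = int(np.count_nonzero(out > flag_cap))
    if n_high:
        logger.info("to_reflectance: %d bands exceed %.2f (specular?)",
                    n_high, flag_cap)
    return sample.with_values(out, extra_flag="calibrated")


def calibrate_cube(cube: HyperCube, region: StandardRegion,
                   bright: HyperCube | None = None,
                   nominal: float | None = None) -> HyperCube:
    """Whole-cube reflectance calibration: optional flat-field, then
    per-pixel division by the standard's median spectrum.

    ``nominal`` defaults to the region's nominal reflectance.  The result
    carries ``meta['calibrated'] = True`` so downstream visual modeling can
    verify it operates on reflectance, not radiance.
    """
    if nominal is None:
        nominal = region.nominal_reflectance
    work = flat_field(cube, bright) if bright is not None else cube
    std = standard_spectrum(work, region).values
    with np.errstate(divide="ignore", invalid="ignore"):
        data = work.data / std[None, None, :] * nominal
    zero = std <= 0
    if zero.any():
        logger.warning("calibrate_cube: %d zero standard bands set to missing",
                       int(zero.sum()))
        data[:, :, zero] = np.nan
    meta = dict(work.meta)
    meta["calibrated"] = True
    return HyperCube(data, cube.wavelengths.copy(), cube.interleave, meta)
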