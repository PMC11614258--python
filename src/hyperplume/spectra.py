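"""Reflectance spectra and their preprocessing.

The preprocessing chain mirrors standard practice for push-broom
hyperspectral reflectance data:

1. piecewise-linear interpolation of each sampled spectrum onto a 1 nm
   grid over the sensor's reliable range (325-700 nm by default);
2. Savitzky-Golay smoothing (45 nm window, polynomial order 2) — heavy
   smoothing chosen to stabilise the short-wavelength extrapolation,
   where small amounts of noise near 325 nm would otherwise produce
   large extrapolation differences;
3. shape-preserving (monotone cubic Hermite) extrapolation of the
   325-700 nm curve down to 300 nm, so spectra cover the full range of
   avian visual sensitivity.

After the full chain a spectrum lives on the integer grid 300..700 nm
(401 points) with the extrapolated region flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

__all__ = [
    "ReflectanceSpectrum",
    "interpolate_1nm",
    "smooth",
    "extrapolate_uv",
    "prepare",
]


@dataclass
class ReflectanceSpectrum:
    """A reflectance spectrum: wavelength grid (nm) + unitless values.

    ``flags`` records the provenance of the values (``raw``,
    ``interpolated``, ``smoothed``, ``extrapolated``); ``extrapolated_mask``
    marks the bands whose values were extrapolated rather than measured.
    Missing bands are represented by NaN.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    flags: frozenset = frozenset({"raw"})
    extrapolated_mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelength and value vectors differ in length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.flags = frozenset(self.flags)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def with_values(self, values, extra_flag=None, extrapolated_mask=None):
        flags = self.flags | {extra_flag} if extra_flag else self.flags
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            flags=flags,
            extrapolated_mask=(self.extrapolated_mask
                               if extrapolated_mask is None else extrapolated_mask),
        )


def _as_array(spec):
    return spec.wavelengths, spec.values


def interpolate_1nm(spec: ReflectanceSpectrum, lo: float = 325.0,
                    hi: float = 700.0) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto the integer-nm grid [lo, hi].

    No extrapolation is performed: the source grid must cover the target
    range, otherwise a coverage error is raised.
    """
    wl, vals = _as_array(spec)
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"source grid [{wl[0]}, {wl[-1]}] nm does not cover [{lo}, {hi}] nm"
        )
    grid = np.arange(lo, hi + 0.5, 1.0)
    out = np.interp(grid, wl, vals)
    return ReflectanceSpectrum(grid, out, spec.flags | {"interpolated"},
                               label=spec.label)


def smooth(spec: ReflectanceSpectrum, window_nm: int = 45,
           polyorder: int = 2) -> ReflectanceSpectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    On a uniform 1 nm grid a 45 nm window is exactly 45 points (odd).
    Edges are handled by refitting the polynomial on the truncated window
    (``mode='interp'``), so a constant spectrum is preserved everywhere and
    any polynomial of degree <= ``polyorder`` is preserved at interior
    points.
    """
    wl, vals = _as_array(spec)
    steps = np.diff(wl)
    if not np.allclose(steps, steps[0]):
        raise ValueError("smoothing requires a uniform wavelength grid")
    window_pts = int(round(window_nm / steps[0]))
    if window_pts % 2 == 0:
        window_pts += 1
    if window_pts > len(vals):
        raise ValueError(
            f"window of {window_pts} points exceeds spectrum length {len(vals)}"
        )
    out = savgol_filter(vals, window_pts, polyorder, mode="interp")
    return spec.with_values(out, extra_flag="smoothed")


def extrapolate_uv(spec: ReflectanceSpectrum, lo: float = 300.0,
                   clamp_factor: float = 1.5) -> ReflectanceSpectrum:
    """Extend a smoothed 325-700 nm spectrum down to ``lo`` (default 300 nm).

    A shape-preserving monotone cubic Hermite interpolant (PCHIP) is fitted
    to the smoothed curve and its leftmost cubic segment evaluated below the
    measured range.  Extrapolated values are clamped to
    ``[0, clamp_factor * max(observed)]`` to keep reflectance physical.
    The result is continuous with the measured value at the left edge.
    """
    wl, vals = _as_array(spec)
    if wl[0] <= lo:
        raise ValueError("spectrum already covers the extrapolation range")
    interp = PchipInterpolator(wl, vals, extrapolate=True)
    new_wl = np.arange(lo, wl[0], 1.0)
    ext = interp(new_wl)
    cap = clamp_factor * float(np.max(vals))
    ext = np.clip(ext, 0.0, cap)
    full_wl = np.concatenate([new_wl, wl])
    full_vals = np.concatenate([ext, vals])
    mask = np.zeros(len(full_wl), dtype=bool)
    mask[: len(new_wl)] = True
    if spec.extrapolated_mask is not None:
        mask[len(new_wl):] = spec.extrapolated_mask
    return ReflectanceSpectrum(full_wl, full_vals,
                               spec.flags | {"extrapolated"},
                               extrapolated_mask=mask, label=spec.label)


def prepare(spec: ReflectanceSpectrum, lo: float = 325.0, hi: float = 700.0,
            uv_lo: float = 300.0, window_nm: int = 45,
            polyorder: int = 2) -> ReflectanceSpectrum:
    """Full preprocessing chain: interpolate -> smooth -> UV-extrapolate.

    Output grid is exactly ``uv_lo..hi`` at 1 nm (401 points for the
    defaults) with the extrapolated region flagged.
    """
    out = interpolate_1nm(spec, lo=lo, hi=hi)
    out = smooth(out, window_nm=window_nm, polyorder=polyorder)
    return extrapolate_uv(out, lo=uv_lo)


def prepare_matrix(wavelengths: np.ndarray, values: np.ndarray,
                   lo: float = 325.0, hi: float = 700.0, uv_lo: float = 300.0,
                   window_nm: int = 45, polyorder: int = 2):
    """Vectorised preprocessing for many spectra at once.

    ``values`` has shape (n_spectra, n_bands) on the common source grid.
    Returns ``(grid, matrix, extrapolated_mask)`` where ``matrix`` has one
    prepared spectrum per row on the integer grid ``uv_lo..hi``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths[0] > lo or wavelengths[-1] < hi:
        raise ValueError("source grid does not cover the interpolation range")
    grid = np.arange(lo, hi + 0.5, 1.0)
    # shared linear-interpolation weights for all spectra
    idx = np.searchsorted(wavelengths, grid, side="right") - 1
    idx = np.clip(idx, 0, len(wavelengths) - 2)
    w = (grid - wavelengths[idx]) / (wavelengths[idx + 1] - wavelengths[idx])
    interp = values[:, idx] * (1 - w) + values[:, idx + 1] * w

    step = 1.0
    window_pts = int(round(window_nm / step))
    if window_pts % 2 == 0:
        window_pts += 1
    smoothed = savgol_filter(interp, window_pts, polyorder, axis=1, mode="interp")

    pchip = PchipInterpolator(grid, smoothed, axis=1, extrapolate=True)
    new_wl = np.arange(uv_lo, lo, 1.0)
    ext = pchip(new_wl)
    cap = 1.5 * smoothed.max(axis=1, keepdims=True)
    ext = np.clip(ext, 0.0, cap)
    full_grid = np.concatenate([new_wl, grid])
    full = np.concatenate([ext, smoothed], axis=1)
    mask = np.zeros(len(full_grid), dtype=bool)
    mask[: len(new_wl)] = True
    return full_grid, full, mask
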