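"""Patch sampling: uniform grids over masks and windowed-median spectra.

Sampling a regular lattice of locations inside each patch mask (rather
than every pixel) controls computational cost and reduces redundancy from
spatial autocorrelation.  The lattice spacing is searched so the number
of locations approximately equalises across patches and specimens; at
each retained location the sample spectrum is the per-band median over a
10x10 pixel window, then spectrally calibrated against the in-scene
standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import StandardRegion, standard_spectrum, to_reflectance
from .cube import HyperCube
from .spectra import ReflectanceSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PatchMask",
    "SampleSet",
    "grid_locations",
    "extract_sample",
    "build_sampleset",
]

META_COLUMNS = ["species", "specimen", "view", "patch", "row", "col"]


@dataclass
class PatchMask:
    """Binary mask delimiting one body patch in one image."""

    mask: np.ndarray
    patch_name: str
    specimen: str = ""
    view: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"patch mask {self.patch_name!r} is empty")


@dataclass
class SampleSet:
    """Table of sampled spectra with species/specimen/view/patch/pixel labels.

    ``meta`` is a DataFrame with columns species, specimen, view, patch,
    row, col; ``spectra`` is the aligned (n_samples, n_bands) value matrix
    on the shared ``wavelengths`` grid.
    """

    meta: pd.DataFrame
    spectra: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.meta) != self.spectra.shape[0]:
            raise ValueError("metadata rows and spectra rows differ")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise ValueError("spectra width and wavelength grid differ")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, mask) -> "SampleSet":
        mask = np.asarray(mask)
        return SampleSet(self.meta[mask].reset_index(drop=True),
                         self.spectra[mask], self.wavelengths)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one DataFrame: metadata columns then one per band."""
        spec = pd.DataFrame(self.spectra,
                            columns=[f"{w:.2f}" for w in self.wavelengths])
        return pd.concat([self.meta.reset_index(drop=True), spec], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(df[META_COLUMNS].copy(), df[wl_cols].to_numpy(float),
                   wavelengths)

    @classmethod
    def concat(cls, parts) -> "SampleSet":
        parts = list(parts)
        wl = parts[0].wavelengths
        for p in parts[1:]:
            if not np.allclose(p.wavelengths, wl):
                raise ValueError("sample sets are on different wavelength grids")
        return cls(pd.concat([p.meta for p in parts], ignore_index=True),
                   np.vstack([p.spectra for p in parts]), wl)


def _lattice_points(mask: np.ndarray, spacing: int) -> np.ndarray:
    """Lattice anchored at the mask bounding-box corner offset by spacing/2,
    intersected with the mask.  Deterministic; no randomness."""
    rows_any = np.flatnonzero(mask.any(axis=1))
    cols_any = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows_any[0], rows_any[-1]
    c0, c1 = cols_any[0], cols_any[-1]
    rr = np.arange(r0 + spacing // 2, r1 + 1, spacing)
    cc = np.arange(c0 + spacing // 2, c1 + 1, spacing)
    if len(rr) == 0 or len(cc) == 0:
        return np.empty((0, 2), dtype=int)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    pts = np.column_stack([grid_r.ravel(), grid_c.ravel()])
    inside = mask[pts[:, 0], pts[:, 1]]
    return pts[inside]


def grid_locations(mask: np.ndarray, target_n: int,
                   tolerance: float = 0.1) -> np.ndarray:
    """Centers of a square lattice over ``mask`` with ~``target_n`` points.

    The spacing starts at ``floor(sqrt(mask_area / target_n))`` and is
    adjusted by +-1 steps until the returned count is within
    ``tolerance`` (default +-10%) of the target or the target is
    bracketed, in which case the closer count wins (ties resolve to the
    smaller spacing, i.e. more samples).  Always returns at least one
    location; fully deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("mask is empty")
    if target_n == 1:
        rows, cols = np.nonzero(mask)
        centroid = np.array([rows.mean(), cols.mean()])
        d2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
        i = int(np.argmin(d2))
        return np.array([[rows[i], cols[i]]])

    lo_n = target_n * (1 - tolerance)
    hi_n = target_n * (1 + tolerance)

    def count(s):
        return len(_lattice_points(mask, s))

    s = max(1, int(np.floor(np.sqrt(area / target_n))))
    n = count(s)
    tried = {s: n}
    # walk toward the target; spacing up lowers the count, down raises it
    while not (lo_n <= n <= hi_n):
        step = 1 if n > hi_n else -1
        s_next = s + step
        if s_next < 1 or s_next in tried:
            break
        n_next = count(s_next)
        tried[s_next] = n_next
        crossed = (n - target_n) * (n_next - target_n) < 0
        s, n = s_next, n_next
        if crossed:
            break
    # pick the tried spacing with count closest to target; tie -> smaller spacing
    best = min(tried.items(),
               key=lambda kv: (abs(kv[1] - target_n) if kv[1] >= 1 else np.inf,
                               kv[0]))
    pts = _lattice_points(mask, best[0])
    if len(pts) == 0:  # degenerate thin masks: fall back to densest lattice
        pts = _lattice_points(mask, 1)
    return pts


def extract_sample(cube: HyperCube, location, window: int = 10) -> ReflectanceSpectrum:
    """Per-band median spectrum over a square window centred at ``location``.

    The default 10x10 window contributes 100 pixels at interior locations;
    at image edges the window is truncated (never discarded) down to a
    minimum of one pixel.
    """
    row, col = int(location[0]), int(location[1])
    if not (0 <= row < cube.lines and 0 <= col < cube.samples):
        raise ValueError(f"location {location} outside image "
                         f"({cube.lines} x {cube.samples})")
    half = window // 2
    r0, r1 = max(0, row - half), min(cube.lines, row - half + window)
    c0, c1 = max(0, col - half), min(cube.samples, col - half + window)
    block = cube.data[r0:r1, c0:c1, :].reshape(-1, cube.bands)
    med = np.nanmedian(block, axis=0)
    return ReflectanceSpectrum(cube.wavelengths, med, flags=frozenset({"raw"}))


@dataclass
class SamplingConfig:
    """Knobs for :func:`build_sampleset`.

    ``target_per_patch`` mirrors the study design of ~1,000 sample spectra
    per patch per specimen (pooled over that specimen's images).
    ``breast_requires_angled`` restricts the named iridescent patch to
    views flagged as angled, where its coloration is actually visible.
    """

    target_per_patch: int = 1000
    window: int = 10
    nominal: float = 1.0
    breast_patch: str = "breast"
    breast_requires_angled: bool = True
    angled_views: tuple = ("ventral_angled", "angled")


def build_sampleset(cube: HyperCube, masks, standard: StandardRegion,
                    config: SamplingConfig | None = None,
                    species: str = "", specimen: str = "",
                    view: str = "") -> SampleSet:
    """Grid -> windowed median -> spectral calibration, for every patch.

    ``masks`` maps patch name to a binary mask (or :class:`PatchMask`).
    Locations falling inside the standard region are excluded (and
    counted in the log) so the white standard never contaminates patch
    samples.
    """
    config = config or SamplingConfig()
    std_spec = standard_spectrum(cube, standard)
    rows = []
    spectra = []
    for name, m in masks.items():
        mask = m.mask if isinstance(m, PatchMask) else np.asarray(m, dtype=bool)
        if mask.shape != cube.data.shape[:2]:
            raise ValueError(f"mask {name!r} shape does not match cube")
        if (config.breast_requires_angled and name == config.breast_patch
                and view not in config.angled_views):
            logger.info("skipping patch %r in non-angled view %r", name, view)
            continue
        usable = mask & ~standard.mask
        n_excluded = int(mask.sum() - usable.sum())
        if n_excluded:
            logger.info("patch %r: %d pixels overlap the standard, excluded",
                        name, n_excluded)
        locs = grid_locations(usable, config.target_per_patch)
        for r, c in locs:
            spec = extract_sample(cube, (r, c), window=config.window)
            cal = to_reflectance(spec, std_spec, nominal=config.nominal)
            rows.append((species, specimen, view, name, int(r), int(c)))
            spectra.append(cal.values)
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return SampleSet(meta, np.array(spectra), cube.wavelengths.copy())
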