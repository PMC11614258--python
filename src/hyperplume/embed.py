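"""Visual-system-independent color space.

Sampled reflectance spectra are embedded without reference to any
viewer's photoreceptors: each spectrum first has its own scalar mean
reflectance subtracted (removing overall brightness so the embedding
responds to spectral *shape*), then PCA compresses the 401-band spectra
to 20 scores, and UMAP maps the PCA coordinates to an interpretable 2-D
plane that attempts to preserve distances.  Kernel-density estimates
over the plane summarise each group's (species') occupied region via
highest-density-region contours, and the spectra nearest each group's
density mode characterise its "most typical" color.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingResult",
    "DensityField",
    "pca_embed",
    "manifold_embed",
    "density_contours",
    "mode_spectra",
    "embed_sampleset",
]


@dataclass
class EmbeddingResult:
    """PCA scores plus (optionally) the 2-D manifold coordinates."""

    pca_coords: np.ndarray
    explained_variance: np.ndarray
    labels: np.ndarray | None = None
    map_coords: np.ndarray | None = None
    seed: int | None = None


@dataclass
class DensityField:
    """Per-group kernel densities over a shared 2-D grid.

    ``density[g]`` integrates to ~1 over the grid; ``level[g]`` is the
    density value whose superlevel set (the highest-density region)
    contains the requested probability mass; ``mode[g]`` is the grid
    argmax.
    """

    xgrid: np.ndarray
    ygrid: np.ndarray
    density: dict
    level: dict
    mode: dict
    mass: float
    bandwidth: dict = field(default_factory=dict)

    @property
    def cell_area(self) -> float:
        return float((self.xgrid[1] - self.xgrid[0])
                     * (self.ygrid[1] - self.ygrid[0]))

    def hdr_mask(self, group) -> np.ndarray:
        """Boolean grid mask of the group's highest-density region."""
        return self.density[group] >= self.level[group]


def pca_embed(spectra: np.ndarray, n_components: int = 20,
              brightness_removal: str = "per_spectrum") -> EmbeddingResult:
    """PCA of brightness-normalised spectra (one call per plumage patch).

    ``brightness_removal='per_spectrum'`` subtracts each spectrum's own
    scalar mean reflectance before the (dataset-mean-centred) PCA, so two
    spectra differing only by a constant offset receive identical
    coordinates.  ``'dataset_mean'`` instead subtracts the dataset mean
    spectrum (plain PCA centring) and keeps brightness information.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[0] < n_components:
        raise ValueError(
            f"need at least {n_components} spectra, got {X.shape[0]}"
        )
    if brightness_removal == "per_spectrum":
        X = X - X.mean(axis=1, keepdims=True)
    elif brightness_removal != "dataset_mean":
        raise ValueError("brightness_removal must be 'per_spectrum' or "
                         "'dataset_mean'")
    n_components = min(n_components, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return EmbeddingResult(pca_coords=coords,
                           explained_variance=pca.explained_variance_ratio_)


def manifold_embed(pca_coords: np.ndarray, seed: int = 42,
                   n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """UMAP the PCA coordinates down to 2-D; deterministic for a fixed seed.

    Degenerate all-identical input collapses to co-located points without
    invoking the manifold machinery.
    """
    X = np.atleast_2d(np.asarray(pca_coords, dtype=float))
    if X.shape[0] < 10:
        raise ValueError("manifold embedding needs at least 10 points")
    if np.ptp(X, axis=0).max() == 0:
        return np.zeros((X.shape[0], 2))
    import umap  # deferred: numba compilation is slow at import time

    n_neighbors = min(n_neighbors, X.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        return np.asarray(reducer.fit_transform(X), dtype=float)


def density_contours(coords: np.ndarray, groups, mass: float = 0.8,
                     grid_size: int = 256, pad: float = 0.1) -> DensityField:
    """Per-group Gaussian KDE over a shared grid, with HDR contour levels.

    Bandwidth is Scott's rule per group; the grid spans the pooled
    bounding box padded by ``pad`` on each side.  The contour level for a
    group is the density value whose superlevel set captures ``mass`` of
    that group's probability (the highest-density region); the mode is
    the grid argmax.  Zero-variance groups receive a jitter floor with a
    warning instead of failing.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    groups = np.asarray(groups)
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    span = np.ptp(coords, axis=0)
    span[span == 0] = 1.0
    lo = coords.min(axis=0) - pad * span
    hi = coords.max(axis=0) + pad * span
    xg = np.linspace(lo[0], hi[0], grid_size)
    yg = np.linspace(lo[1], hi[1], grid_size)
    XX, YY = np.meshgrid(xg, yg, indexing="ij")
    eval_pts = np.vstack([XX.ravel(), YY.ravel()])
    cell = (xg[1] - xg[0]) * (yg[1] - yg[0])

    density, level, mode, bandwidth = {}, {}, {}, {}
    for g in np.unique(groups):
        pts = coords[groups == g].T  # (2, n)
        if pts.shape[1] < 10:
            raise ValueError(f"group {g!r} has fewer than 10 points")
        try:
            kde = gaussian_kde(pts)
        except np.linalg.LinAlgError:
            logger.warning("group %r is singular; applying jitter floor", g)
            jitter = 1e-6 * max(1.0, np.abs(pts).max())
            rng = np.random.default_rng(0)
            kde = gaussian_kde(pts + rng.normal(0, jitter, pts.shape))
        d = kde(eval_pts).reshape(grid_size, grid_size)
        total = d.sum() * cell
        if total > 0:
            d = d / total  # renormalise mass truncated by the grid
        density[g] = d
        bandwidth[g] = kde.factor
        if mass >= 1.0:
            level[g] = 0.0
        else:
            flat = np.sort(d.ravel())[::-1]
            cum = np.cumsum(flat) * cell
            k = int(np.searchsorted(cum, mass))
            level[g] = float(flat[min(k, len(flat) - 1)])
        i, j = np.unravel_index(np.argmax(d), d.shape)
        mode[g] = np.array([xg[i], yg[j]])
    return DensityField(xg, yg, density, level, mode, mass, bandwidth)


def mode_spectra(field: DensityField, coords: np.ndarray, groups,
                 spectra: np.ndarray, k: int = 50) -> dict:
    """For each group, the ``k`` nearest samples (2-D Euclidean) to its
    density mode, with their per-band median and median absolute deviation.

    ``k`` larger than the group is capped with a warning.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    groups = np.asarray(groups)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    out = {}
    for g, m in field.mode.items():
        idx = np.flatnonzero(groups == g)
        kk = k
        if kk > len(idx):
            logger.warning("group %r: k=%d exceeds group size %d; capped",
                           g, k, len(idx))
            kk = len(idx)
        d2 = ((coords[idx] - m) ** 2).sum(axis=1)
        nearest = idx[np.argsort(d2, kind="stable")[:kk]]
        sel = spectra[nearest]
        med = np.median(sel, axis=0)
        mad = np.median(np.abs(sel - med), axis=0)
        out[g] = {"indices": nearest, "spectra": sel, "median": med, "mad": mad}
    return out


def embed_sampleset(spectra: np.ndarray, seed: int = 42, n_components: int = 20,
                    n_neighbors: int = 15, min_dist: float = 0.1,
                    brightness_removal: str = "per_spectrum") -> EmbeddingResult:
    """Convenience chain: brightness removal -> PCA -> UMAP."""
    res = pca_embed(spectra, n_components=n_components,
                    brightness_removal=brightness_removal)
    res.map_coords = manifold_embed(res.pca_coords, seed=seed,
                                    n_neighbors=n_neighbors, min_dist=min_dist)
    res.seed = seed
    return res
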