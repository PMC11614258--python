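"""Synthetic hyperspectral scenes with known ground truth.

Every pipeline stage is testable without museum data: the generator
emulates a push-broom acquisition of a specimen-style scene — a white
reflectance standard, several uniform-ish color patches with known
reflectance spectra, a directional-lighting brightness gradient across
the field of view, and additive Gaussian sensor noise.  The default
wavelength grid (294 bands, 274-812 nm, ~1.83 nm spacing) matches the
instrument class the pipeline targets, so interpolation arithmetic is
exercised exactly as with real cubes.

Default patch spectra are chosen to mimic common plumage reflectance
classes: a carotenoid-like long-pass sigmoid step, a structural-green
Gaussian peak, flat white, and a brown linear ramp — all broad, as
natural plumage curves are.

:func:`simulate_scene3d` additionally builds an ellipsoid "specimen"
whose iridescent patch shifts its peak wavelength linearly with the
surface-normal pitch, together with landmark correspondences for pose
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import StandardRegion
from .cube import HyperCube
from .geometry3d import LandmarkSet
from .spectra import ReflectanceSpectrum

__all__ = [
    "PatchSpec",
    "SceneSpec",
    "GroundTruth",
    "spectrum_model",
    "simulate_cube",
    "simulate_scene3d",
    "default_scene",
]

DEFAULT_GRID = np.linspace(274.0, 812.0, 294)


def spectrum_model(kind: str, params: dict,
                   wavelengths: np.ndarray = DEFAULT_GRID) -> ReflectanceSpectrum:
    """Deterministic parametric reflectance spectra.

    Kinds: ``sigmoid_step(l0, steepness, lo, hi)`` (carotenoid-like
    long-pass edge), ``gaussian_peak(l0, sigma, amplitude, baseline)``
    (structural green/blue), ``flat(level)``, ``linear_ramp(lo, hi)``
    (melanin/brown).  Parameters producing reflectance outside [0, 1]
    are rejected.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if kind == "sigmoid_step":
        l0 = params.get("l0", 550.0)
        s = params.get("steepness", 25.0)
        lo = params.get("lo", 0.05)
        hi = params.get("hi", 0.6)
        vals = lo + (hi - lo) / (1.0 + np.exp(-(wl - l0) / s))
    elif kind == "gaussian_peak":
        l0 = params.get("l0", 530.0)
        sigma = params.get("sigma", 50.0)
        amp = params.get("amplitude", 0.45)
        base = params.get("baseline", 0.05)
        vals = base + amp * np.exp(-((wl - l0) ** 2) / (2 * sigma ** 2))
    elif kind == "flat":
        vals = np.full_like(wl, params.get("level", 0.5))
    elif kind == "linear_ramp":
        lo = params.get("lo", 0.05)
        hi = params.get("hi", 0.35)
        vals = lo + (hi - lo) * (wl - wl[0]) / (wl[-1] - wl[0])
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError(f"{kind} parameters produce reflectance outside [0, 1]")
    return ReflectanceSpectrum(wl, vals, label=kind)


@dataclass
class PatchSpec:
    """One synthetic patch: a region, a spectrum model, and (optionally)
    an angle-dependence coefficient in nm of peak shift per radian of
    pitch."""

    name: str
    shape: str  # 'rect' or 'ellipse'
    region: tuple  # rect: (r0, r1, c0, c1); ellipse: (rc, cc, rr, cr)
    kind: str = "flat"
    params: dict = field(default_factory=dict)
    angle_coeff: float = 0.0

    def mask(self, image_shape) -> np.ndarray:
        lines, samples = image_shape
        m = np.zeros((lines, samples), dtype=bool)
        if self.shape == "rect":
            r0, r1, c0, c1 = self.region
            m[r0:r1, c0:c1] = True
        elif self.shape == "ellipse":
            rc, cc, rr, cr = self.region
            r, c = np.ogrid[:lines, :samples]
            m[((r - rc) / rr) ** 2 + ((c - cc) / cr) ** 2 <= 1.0] = True
        else:
            raise ValueError(f"unknown patch shape {self.shape!r}")
        return m


@dataclass
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes everything."""

    image_shape: tuple = (160, 220)
    patches: list = field(default_factory=list)
    standard_region: tuple = (10, 40, 10, 60)  # (r0, r1, c0, c1)
    standard_nominal: float = 0.99
    gradient_amplitude: float = 0.2
    illuminant_level: float = 1.0
    noise_sd: float = 0.01
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        shape = self.image_shape
        std = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.standard_region
        std[r0:r1, c0:c1] = True
        taken = std.copy()
        for p in self.patches:
            m = p.mask(shape)
            if (m & taken).any():
                raise ValueError(f"patch {p.name!r} overlaps another region")
            taken |= m


@dataclass
class GroundTruth:
    """Everything the generator knows: per-patch spectra, masks, gradient."""

    spectra: dict
    masks: dict
    gradient: np.ndarray
    standard: StandardRegion
    extras: dict = field(default_factory=dict)


def default_scene(noise_sd: float = 0.01, gradient_amplitude: float = 0.2,
                  seed: int = 0) -> SceneSpec:
    """The stock four-patch layout: white standard plus breast (structural
    green), shoulder (orange carotenoid step), back (red-shifted step),
    and belly (flat off-white)."""
    patches = [
        PatchSpec("breast", "ellipse", (70, 50, 22, 28), "gaussian_peak",
                  {"l0": 535.0, "sigma": 50.0, "amplitude": 0.45,
                   "baseline": 0.05}),
        PatchSpec("shoulder", "rect", (45, 90, 100, 160), "sigmoid_step",
                  {"l0": 545.0, "steepness": 25.0, "lo": 0.05, "hi": 0.6}),
        PatchSpec("back", "rect", (110, 150, 20, 100), "sigmoid_step",
                  {"l0": 595.0, "steepness": 28.0, "lo": 0.04, "hi": 0.55}),
        PatchSpec("belly", "ellipse", (120, 165, 25, 40), "flat",
                  {"level": 0.65}),
    ]
    return SceneSpec(patches=patches, noise_sd=noise_sd,
                     gradient_amplitude=gradient_amplitude, seed=seed)


def simulate_cube(spec: SceneSpec):
    """Render a radiance cube (plus its bright reference) from a scene.

    radiance = illuminant x column-gradient x reflectance + noise.  The
    bright cube images a unit-reflectance white block under the same
    illumination, so flat-fielding with it removes the gradient exactly.
    Returns ``(cube, bright, truth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lines, samples = spec.image_shape
    wl = np.asarray(spec.wavelengths, dtype=float)
    bands = len(wl)

    gradient = 1.0 + spec.gradient_amplitude * np.linspace(-1.0, 1.0, samples)
    illum = spec.illuminant_level * gradient  # (samples,)

    reflectance = np.full((lines, samples, bands), 0.02)  # dark background
    masks = {}
    spectra = {}
    for p in spec.patches:
        m = p.mask(spec.image_shape)
        masks[p.name] = m
        s = spectrum_model(p.kind, p.params, wl)
        spectra[p.name] = s
        reflectance[m] = s.values
    std_mask = np.zeros(spec.image_shape, dtype=bool)
    r0, r1, c0, c1 = spec.standard_region
    std_mask[r0:r1, c0:c1] = True
    std_spec = spectrum_model("flat", {"level": spec.standard_nominal}, wl)
    reflectance[std_mask] = std_spec.values
    masks["standard"] = std_mask
    spectra["standard"] = std_spec

    radiance = reflectance * illum[None, :, None]
    if spec.noise_sd > 0:
        radiance = radiance + rng.normal(0.0, spec.noise_sd, radiance.shape)
    radiance = np.clip(radiance, 0.0, None)
    cube = HyperCube(radiance, wl.copy(), meta={"description": "synthetic scene",
                                                "seed": spec.seed})

    bright_lines = 8
    bright_data = np.broadcast_to(
        illum[None, :, None], (bright_lines, samples, bands)).copy()
    bright = HyperCube(bright_data, wl.copy(),
                       meta={"description": "synthetic bright reference"})

    truth = GroundTruth(spectra=spectra, masks=masks, gradient=gradient,
                        standard=StandardRegion(std_mask,
                                                spec.standard_nominal))
    return cube, bright, truth


def _ellipsoid_mesh(semi_axes, subdivisions: int = 4):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    mesh.apply_scale(semi_axes)
    return mesh


def simulate_scene3d(image_shape=(160, 200), semi_axes=(60.0, 70.0, 45.0),
                     scale: float = 1.0, peak_l0: float = 550.0,
                     angle_coeff: float = 100.0, noise_sd: float = 0.0,
                     wavelengths: np.ndarray = DEFAULT_GRID, seed: int = 0,
                     subdivisions: int = 4):
    """Ellipsoid specimen with an angle-dependent (iridescent) coat.

    The ellipsoid (semi-axes in mesh units) is viewed orthographically at
    ``scale`` pixels per unit, centred in the image.  Per-pixel pitch
    follows from the analytic ellipsoid normal; the coat is a Gaussian
    peak whose centre shifts as ``peak_l0 - angle_coeff * pitch`` (nm per
    radian).  Returns ``(mesh, landmarks, cube, truth)`` where the truth
    bundle carries the analytic pitch map and the shift coefficient.
    """
    rng = np.random.default_rng(seed)
    lines, samples = image_shape
    wl = np.asarray(wavelengths, dtype=float)
    a, b, c = semi_axes
    mesh = _ellipsoid_mesh(semi_axes, subdivisions)

    center = np.array([samples / 2.0, lines / 2.0])  # (col, row)
    # camera frame: x -> col, y -> row, z -> toward camera (identity pose)
    col_grid, row_grid = np.meshgrid(np.arange(samples), np.arange(lines))
    x = (col_grid - center[0]) / scale
    y = (row_grid - center[1]) / scale
    inside = (x / a) ** 2 + (y / b) ** 2 < 1.0
    z = np.zeros_like(x)
    z[inside] = c * np.sqrt(1.0 - (x[inside] / a) ** 2 - (y[inside] / b) ** 2)
    # outward ellipsoid normal at (x, y, z): (x/a^2, y/b^2, z/c^2)
    n_x = np.where(inside, x / a ** 2, 0.0)
    n_y = np.where(inside, y / b ** 2, 0.0)
    n_z = np.where(inside, z / c ** 2, 1.0)
    norm = np.sqrt(n_x ** 2 + n_y ** 2 + n_z ** 2)
    n_x, n_y, n_z = n_x / norm, n_y / norm, n_z / norm
    pitch = np.where(inside, np.arctan2(-n_y, n_z), np.nan)
    roll = np.where(inside, np.arctan2(-n_x, n_z), np.nan)

    reflectance = np.full((lines, samples, len(wl)), 0.02)
    l0_map = peak_l0 - angle_coeff * np.where(inside, pitch, 0.0)
    sigma, amp, base = 45.0, 0.5, 0.05
    rr, cc = np.nonzero(inside)
    vals = base + amp * np.exp(
        -((wl[None, :] - l0_map[rr, cc][:, None]) ** 2) / (2 * sigma ** 2))
    reflectance[rr, cc] = vals
    if noise_sd > 0:
        reflectance = np.clip(
            reflectance + rng.normal(0.0, noise_sd, reflectance.shape),
            0.0, None)
    cube = HyperCube(reflectance, wl.copy(),
                     meta={"description": "synthetic 3d scene",
                           "calibrated": True, "seed": seed})

    # landmarks: front pole plus four rim-adjacent surface points
    lm_mesh = np.array([
        [0.0, 0.0, c],
        [a * 0.8, 0.0, c * np.sqrt(1 - 0.8 ** 2)],
        [-a * 0.8, 0.0, c * np.sqrt(1 - 0.8 ** 2)],
        [0.0, b * 0.8, c * np.sqrt(1 - 0.8 ** 2)],
        [0.0, -b * 0.6, c * np.sqrt(1 - 0.6 ** 2)],
    ])
    lm_img = np.column_stack([
        lm_mesh[:, 1] * scale + center[1],  # row
        lm_mesh[:, 0] * scale + center[0],  # col
    ])
    landmarks = LandmarkSet(lm_img, lm_mesh,
                            names=["pole", "right", "left", "bottom", "top"])

    truth = {
        "pitch": pitch, "roll": roll, "inside": inside,
        "angle_coeff": angle_coeff, "peak_l0": peak_l0,
        "sigma": sigma, "scale": scale, "center": center,
    }
    return mesh, landmarks, cube, truth
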