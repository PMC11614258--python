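"""Visual-system-dependent modeling for tetrachromatic (avian) viewers.

Given a reflectance spectrum R(lambda) on the 300-700 nm grid and a set
of photoreceptor sensitivities S_i(lambda), the quantum catch of
receptor i under an ideal (flat) illuminant with von-Kries adaptation to
an ideal white background is

    Q_i = sum_lambda R(lambda) S_i(lambda) / sum_lambda S_i(lambda),

so a perfect white yields Q_i = 1 for every receptor.  Relative catches
q_i = Q_i / sum_j Q_j map to 3-D coordinates in the avian tetrahedral
color space (achromatic center at the origin, the four pure-receptor
vertices at radius 0.75).

Discriminability is assessed with the receptor-noise-limited (RNL)
model: log-catch differences Delta f_i = ln(Q_i^A / Q_i^B) are weighted
by per-channel noise e_i = w * sqrt(n_max / n_i), where w is the Weber
fraction of the most abundant cone class and n_i the relative cone
abundances.  The resulting chromatic distance dS is in just-noticeable-
difference-like units; the luminance contrast dL = |ln(Q_D^A/Q_D^B)|/w_D
uses the (double-cone) achromatic channel.  Following common practice
for museum-specimen comparisons, two colors are called discriminable
when the contrast is >= 3.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import HyperCube
from .spectra import ReflectanceSpectrum, prepare_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReceptorSystem",
    "ConeCatch",
    "govardovskii_template",
    "vs_bird_receptors",
    "quantum_catch",
    "tetra_coords",
    "rnl_chromatic",
    "rnl_luminance",
    "discriminable",
    "cone_catch_image",
    "patch_contrasts",
]

RECEPTOR_NAMES = ("vs", "sws", "mws", "lws")

# Template lambda-max (nm) for an average violet-sensitive (VS) bird,
# generated from the Govardovskii A1 nomogram.  Values follow the
# commonly used average-VS effective peak positions (violet ~417 nm,
# short ~478 nm, medium ~542 nm, long ~607 nm); they are configurable
# because published systems vary by species.
AVERAGE_VS_LMAX = {"vs": 417.0, "sws": 478.0, "mws": 542.0, "lws": 607.0}
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

CATCH_FLOOR = 1e-9  # floor before logs, avoids -inf on black pixels


@dataclass
class ReceptorSystem:
    """Receptor sensitivities, cone abundances, and Weber fractions.

    ``sensitivities`` is (4, n_wavelengths) in the order VS, SWS, MWS,
    LWS, each curve non-negative and peak-normalised to 1.  ``abundances``
    defaults to the (1, 1, 1, 2) cone-ratio values reported for Rock
    dove; ``weber`` (chromatic, anchored to the most abundant cone class)
    and ``weber_achro`` both default to 0.1.  ``double`` optionally holds
    a double-cone sensitivity used for the luminance channel; when absent
    the LWS curve stands in as a proxy.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray
    double: np.ndarray | None = None
    abundances: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0, 1.0, 2.0]))
    weber: float = 0.1
    weber_achro: float = 0.1
    names: tuple = RECEPTOR_NAMES

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.sensitivities.shape != (4, len(self.wavelengths)):
            raise ValueError("sensitivities must be (4, n_wavelengths)")
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(self.abundances <= 0) or self.weber <= 0 or self.weber_achro <= 0:
            raise ValueError("abundances and Weber fractions must be positive")

    @property
    def noise(self) -> np.ndarray:
        """Per-channel RNL noise e_i = w * sqrt(n_max / n_i)."""
        n = self.abundances
        return self.weber * np.sqrt(n.max() / n)

    @property
    def luminance_sensitivity(self) -> np.ndarray:
        return self.double if self.double is not None else self.sensitivities[3]

    def to_frame(self) -> pd.DataFrame:
        cols = {"wavelength_nm": self.wavelengths}
        for name, s in zip(self.names, self.sensitivities):
            cols[name] = s
        if self.double is not None:
            cols["dbl"] = self.double
        return pd.DataFrame(cols)


@dataclass
class ConeCatch:
    """Raw catches Q_i, relative catches q_i, tetrahedral coordinates."""

    Q: np.ndarray
    q: np.ndarray
    xyz: np.ndarray
    Q_double: float | None = None


def govardovskii_template(lmax: float,
                          wavelengths: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """A1 visual-pigment absorbance template (Govardovskii et al. 2000).

    Alpha band plus beta band, peak-normalised to 1.  ``lmax`` is the
    alpha-band peak in nm and must lie inside the wavelength grid.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (wavelengths[0] <= lmax <= wavelengths[-1]):
        raise ValueError(f"lambda-max {lmax} nm outside grid "
                         f"[{wavelengths[0]}, {wavelengths[-1]}] nm")
    x = lmax / wavelengths
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    b, c = 0.922, 1.104
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x))
                   + np.exp(C * (c - x)) + D)
    lmax_beta = 189.0 + 0.315 * lmax
    b_beta = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wavelengths - lmax_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


def vs_bird_receptors(lmax: dict | None = None,
                      wavelengths: np.ndarray = DEFAULT_GRID,
                      double_lmax: float | None = None,
                      abundances=(1.0, 1.0, 1.0, 2.0),
                      weber: float = 0.1,
                      weber_achro: float = 0.1) -> ReceptorSystem:
    """Receptor system for an average violet-sensitive (VS) bird.

    Sensitivity curves are synthesized from the Govardovskii A1 nomogram
    at the lambda-max values in ``lmax`` (default
    :data:`AVERAGE_VS_LMAX`); they are template approximations, not
    measured curves, and every peak position is user-configurable.  The
    double cone (luminance channel) defaults to the LWS template peak.
    """
    lm = dict(AVERAGE_VS_LMAX)
    if lmax:
        lm.update(lmax)
    sens = np.vstack([govardovskii_template(lm[n], wavelengths)
                      for n in RECEPTOR_NAMES])
    dbl = govardovskii_template(double_lmax, wavelengths) \
        if double_lmax is not None else None
    return ReceptorSystem(wavelengths, sens, double=dbl,
                          abundances=np.asarray(abundances, float),
                          weber=weber, weber_achro=weber_achro)


def quantum_catch(spec: ReflectanceSpectrum, rec: ReceptorSystem) -> ConeCatch:
    """Quantum catches of a reflectance spectrum under an ideal illuminant.

    The spectrum must share the receptor system's wavelength grid (use
    the preprocessing chain to reach 300-700 nm at 1 nm first).
    """
    if len(spec.wavelengths) != len(rec.wavelengths) or not np.allclose(
            spec.wavelengths, rec.wavelengths):
        raise ValueError("spectrum and receptor system are on different grids")
    R = spec.values
    S = rec.sensitivities
    Q = (S * R[None, :]).sum(axis=1) / S.sum(axis=1)
    q = Q / Q.sum() if Q.sum() > 0 else np.full(4, 0.25)
    Sd = rec.luminance_sensitivity
    Q_d = float((Sd * R).sum() / Sd.sum())
    return ConeCatch(Q=Q, q=q, xyz=tetra_coords(q), Q_double=Q_d)


def tetra_coords(q) -> np.ndarray:
    """Tetrahedral color-space coordinates from relative catches.

    ``q`` is (u, s, m, l) = (VS, SWS, MWS, LWS) with sum 1.  The
    published convention places the achromatic point at the origin and
    all four pure-receptor vertices at distance 0.75:

        x = ((1 - 2s - m - u) / 2) * sqrt(3/2)
        y = (-1 + 3m + u) / (2 sqrt 2)
        z = u - 1/4
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError("q must have four components (VS, SWS, MWS, LWS)")
    if np.any(q < -1e-12) or not np.allclose(q.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("relative catches must be non-negative and sum to 1")
    u, s, m = q[..., 0], q[..., 1], q[..., 2]
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(1.5)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    return np.stack([x, y, z], axis=-1)


def _delta_f(QA, QB) -> np.ndarray:
    QA = np.asarray(QA, dtype=float)
    QB = np.asarray(QB, dtype=float)
    if np.any(QA < 0) or np.any(QB < 0):
        raise ValueError("catches must be non-negative (floor applied at "
                         f"{CATCH_FLOOR})")
    n_floored = int((QA < CATCH_FLOOR).sum() + (QB < CATCH_FLOOR).sum())
    if n_floored:
        logger.info("catch floor %g applied to %d channels", CATCH_FLOOR,
                    n_floored)
    return np.log(np.maximum(QA, CATCH_FLOOR) / np.maximum(QB, CATCH_FLOOR))


def rnl_chromatic(QA, QB, rec: ReceptorSystem) -> float:
    """Receptor-noise-limited chromatic contrast dS between two catches.

    Tetrachromatic form: with Delta f_i = ln(Q_i^A / Q_i^B) and noise
    e_i, dS^2 is the ratio of the six pairwise terms
    e_k^2 e_l^2 (Delta f_i - Delta f_j)^2 (k, l the complementary pair)
    to the four triple products (e_i e_j e_k)^2.  Because only
    differences of Delta f enter, dS is invariant to overall brightness
    scaling of either spectrum.
    """
    f = _delta_f(QA, QB)
    e = rec.noise
    idx = range(4)
    num = 0.0
    for i, j in itertools.combinations(idx, 2):
        k, l = [m for m in idx if m not in (i, j)]
        num += (e[k] * e[l]) ** 2 * (f[i] - f[j]) ** 2
    den = sum(np.prod([e[m] for m in idx if m != leave]) ** 2 for leave in idx)
    return float(np.sqrt(num / den))


def rnl_luminance(QA_d: float, QB_d: float, rec: ReceptorSystem) -> float:
    """Achromatic (luminance) contrast dL = |ln(Q_A / Q_B)| / w_D."""
    f = _delta_f(QA_d, QB_d)
    return float(np.abs(f) / rec.weber_achro)


def discriminable(contrast: float, threshold: float = 3.0) -> bool:
    """True when the contrast meets the threshold (inclusive at 3.0)."""
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    return bool(contrast >= threshold)


def cone_catch_image(cube: HyperCube, rec: ReceptorSystem,
                     uv_mode: str = "pchip", force: bool = False) -> np.ndarray:
    """Per-pixel quantum catches of a calibrated reflectance cube.

    Each pixel spectrum is run through the standard preprocessing chain
    (interpolation, smoothing, UV extrapolation; ``uv_mode='constant'``
    instead extends the 325 nm value flat) and integrated against the
    receptor sensitivities.  Returns (lines, samples, 4) — or
    (lines, samples, 5) when a double cone is present, with the
    achromatic channel last.  Refuses uncalibrated cubes unless
    ``force=True``.
    """
    if not cube.meta.get("calibrated") and not force:
        raise ValueError("cube does not appear to be reflectance-calibrated; "
                         "pass force=True to override")
    flat = cube.data.reshape(-1, cube.bands)
    if uv_mode == "pchip":
        grid, prepped, _ = prepare_matrix(cube.wavelengths, flat)
    elif uv_mode == "constant":
        grid, body, _ = prepare_matrix(cube.wavelengths, flat, uv_lo=325.0)
        n_uv = int(grid[0] - 300.0)
        grid = np.concatenate([np.arange(300.0, grid[0], 1.0), grid])
        prepped = np.concatenate(
            [np.repeat(body[:, :1], n_uv, axis=1), body], axis=1)
    else:
        raise ValueError("uv_mode must be 'pchip' or 'constant'")
    if len(grid) != len(rec.wavelengths) or not np.allclose(
            grid, rec.wavelengths):
        raise ValueError("prepared grid does not match receptor grid")
    S = rec.sensitivities
    Q = prepped @ S.T / S.sum(axis=1)[None, :]
    channels = [Q]
    if rec.double is not None:
        Sd = rec.double
        channels.append((prepped @ Sd / Sd.sum())[:, None])
    out = np.concatenate(channels, axis=1)
    return out.reshape(cube.lines, cube.samples, -1)


def write_cone_image(path, catches: np.ndarray, rec: ReceptorSystem) -> None:
    """Export per-pixel catches as a 32-bit multichannel TIFF with channel
    names in the ImageJ-style metadata."""
    import tifffile

    names = list(rec.names) + (["dbl"] if catches.shape[-1] == 5 else [])
    tifffile.imwrite(path, catches.astype(np.float32).transpose(2, 0, 1),
                     imagej=True,
                     metadata={"axes": "CYX", "Labels": names})


def patch_contrasts(sampleset, rec: ReceptorSystem,
                    threshold: float = 3.0) -> pd.DataFrame:
    """Pairwise RNL contrasts between specimens, per patch.

    Uses the median spectrum for each patch on each specimen (the usual
    single-spectrum simplification) and reports dS, dL, and the
    discriminability calls at ``threshold``.
    """
    meta, spectra = sampleset.meta, sampleset.spectra
    wl = sampleset.wavelengths
    med = {}
    for (spec_id, patch), idx in meta.groupby(["specimen", "patch"]).groups.items():
        med[(spec_id, patch)] = np.median(spectra[np.asarray(idx)], axis=0)
    rows = []
    for patch in sorted(meta["patch"].unique()):
        specimens = sorted({s for (s, p) in med if p == patch})
        catches = {s: quantum_catch(
            ReflectanceSpectrum(wl, med[(s, patch)]), rec)
            for s in specimens}
        for a, b in itertools.combinations(specimens, 2):
            ds = rnl_chromatic(catches[a].Q, catches[b].Q, rec)
            dl = rnl_luminance(catches[a].Q_double, catches[b].Q_double, rec)
            rows.append({
                "specimenA": a, "specimenB": b, "patch": patch,
                "dS": ds, "dL": dl,
                "discriminable_dS": discriminable(ds, threshold),
                "discriminable_dL": discriminable(dl, threshold),
            })
    return pd.DataFrame(rows)
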