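"""Spectral phasor analysis of hyperspectral stacks.

Each pixel's emission spectrum I_k (k = 0..K-1, k = 0 at the shortest
wavelength) is mapped to the first Fourier harmonic normalized by total
intensity:

    G = sum_k I_k cos(2*pi*h*k/K) / sum_k I_k
    S = sum_k I_k sin(2*pi*h*k/K) / sum_k I_k

The angular position Phi = atan2(S, G) tracks the spectral center of mass (a
red shift moves the phasor counterclockwise, Phi increases) and the radial
position M = sqrt(G^2 + S^2) shrinks with spectral broadening; every
nonnegative spectrum lands inside the unit circle.  The phasor of a sum of
spectra is the intensity-weighted mean of the component phasors, which makes
two-reference linear-combination (fraction) analysis exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ConfigurationError
from .synthgen import SpectralScene

__all__ = [
    "PhasorPoint",
    "PhasorField",
    "FractionCurve",
    "spectral_phasor",
    "phasor_summary",
    "linear_fraction",
    "fraction_curve",
    "phasor_of_spectrum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhasorPoint:
    G: float
    S: float

    @property
    def Phi(self) -> float:
        return float(np.arctan2(self.S, self.G))

    @property
    def M(self) -> float:
        return float(np.hypot(self.G, self.S))


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates of a spectral stack."""

    G: np.ndarray
    S: np.ndarray
    total_intensity: np.ndarray
    valid: np.ndarray
    harmonic: int
    wavelengths_nm: np.ndarray

    @property
    def Phi(self) -> np.ndarray:
        return np.arctan2(self.S, self.G)

    @property
    def M(self) -> np.ndarray:
        return np.hypot(self.G, self.S)


@dataclass
class FractionCurve:
    """Normalized pixel-intensity histogram over the two-component fraction
    axis, with its (intensity-weighted) center of mass."""

    bin_centers: np.ndarray
    values: np.ndarray          # normalized to unit maximum
    center_of_mass: float
    degenerate: bool = False


def phasor_of_spectrum(spectrum: np.ndarray, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a single spectrum (K,) — convenience for references."""
    spectrum = np.asarray(spectrum, dtype=float)
    k = np.arange(len(spectrum))
    ang = 2.0 * np.pi * harmonic * k / len(spectrum)
    tot = spectrum.sum()
    if tot <= 0:
        raise ConfigurationError("spectrum has no intensity")
    return PhasorPoint(float((spectrum * np.cos(ang)).sum() / tot),
                       float((spectrum * np.sin(ang)).sum() / tot))


def spectral_phasor(scene: SpectralScene, harmonic: int = 1,
                    intensity_threshold: float | None = None) -> PhasorField:
    """Per-pixel first-harmonic (G, S) of a hyperspectral scene.

    Pixels with total intensity <= threshold are marked invalid.  With
    ``intensity_threshold=None`` the threshold is Otsu on the total-intensity
    image (restricted to labeled-cell pixels when labels are present).
    """
    stack = scene.stack
    if stack.shape[2] < 2:
        raise ConfigurationError("need at least 2 spectral channels")
    if harmonic < 1:
        raise ConfigurationError("harmonic must be >= 1")
    if np.any(stack < 0):
        raise ConfigurationError("negative intensities: corrupted stack")
    K = stack.shape[2]
    ang = 2.0 * np.pi * harmonic * np.arange(K) / K
    total = stack.sum(axis=2)
    if intensity_threshold is None:
        ref = total[scene.labels > 0] if np.any(scene.labels > 0) else total.ravel()
        try:
            intensity_threshold = float(threshold_otsu(ref))
        except ValueError:  # constant image
            intensity_threshold = 0.0
    if intensity_threshold < 0:
        raise ConfigurationError("intensity threshold must be >= 0")
    valid = total > intensity_threshold
    if not valid.any():
        raise ConfigurationError("no pixel exceeds the intensity threshold")
    safe = np.where(total > 0, total, 1.0)
    G = np.where(valid, stack @ np.cos(ang) / safe, 0.0)
    S = np.where(valid, stack @ np.sin(ang) / safe, 0.0)
    return PhasorField(G, S, total, valid, harmonic, scene.wavelengths_nm.copy())


def phasor_summary(field: PhasorField,
                   labels: np.ndarray | None = None) -> dict[int, dict[str, float]]:
    """Intensity-weighted per-group phasor summaries.

    Returns ``{group: {n, mean_G, mean_S, mean_Phi, mean_M, dispersion}}``;
    group 0 covers the whole field when no labels are given.  Dispersion is
    the intensity-weighted RMS distance from the group mean in the (G, S)
    plane.  Empty groups are skipped with a log message.
    """
    out: dict[int, dict[str, float]] = {}
    if labels is None:
        groups = {0: field.valid}
    else:
        groups = {int(g): (labels == g) & field.valid
                  for g in np.unique(labels) if g != 0}
    for g, sel in groups.items():
        if not sel.any():
            logger.info("phasor summary: group %s has no valid pixels, skipped", g)
            continue
        w = field.total_intensity[sel]
        W = w.sum()
        mg = float((w * field.G[sel]).sum() / W)
        ms = float((w * field.S[sel]).sum() / W)
        disp = float(np.sqrt((w * ((field.G[sel] - mg) ** 2
                                   + (field.S[sel] - ms) ** 2)).sum() / W))
        out[g] = {
            "n": int(sel.sum()),
            "mean_G": mg,
            "mean_S": ms,
            "mean_Phi": float(np.arctan2(ms, mg)),
            "mean_M": float(np.hypot(mg, ms)),
            "dispersion": disp,
        }
    return out


def linear_fraction(field: PhasorField, ref_a: PhasorPoint,
                    ref_b: PhasorPoint) -> np.ndarray:
    """Fraction of component A per pixel by orthogonal projection of (G, S)
    onto the segment ref_b -> ref_a, clipped to [0, 1].

    A pixel at ``ref_a`` maps to 1, at ``ref_b`` to 0.  Invalid pixels are
    NaN."""
    a = np.array([ref_a.G, ref_a.S])
    b = np.array([ref_b.G, ref_b.S])
    d = a - b
    nrm2 = float(d @ d)
    if nrm2 < 1e-24:
        raise ConfigurationError("degenerate references: ref_a == ref_b")
    t = ((field.G - b[0]) * d[0] + (field.S - b[1]) * d[1]) / nrm2
    frac = np.clip(t, 0.0, 1.0)
    return np.where(field.valid, frac, np.nan)


def fraction_curve(field: PhasorField, fractions: np.ndarray,
                   bins: int = 20) -> FractionCurve:
    """Pixel-intensity histogram over fraction bins on [0, 1].

    The curve is normalized to unit maximum; the center of mass is computed
    on the unnormalized intensity mass.  A curve whose mass is entirely
    clipped onto one endpoint bin is flagged degenerate."""
    if bins < 2:
        raise ConfigurationError("bins must be >= 2")
    sel = field.valid & np.isfinite(fractions)
    f = fractions[sel]
    w = field.total_intensity[sel]
    hist, edges = np.histogram(f, bins=bins, range=(0.0, 1.0), weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mass = hist.sum()
    com = float((centers * hist).sum() / mass) if mass > 0 else float("nan")
    nz = np.flatnonzero(hist)
    degenerate = len(nz) <= 1 and (len(nz) == 0 or nz[0] in (0, bins - 1))
    if degenerate:
        logger.warning("fraction curve degenerate: all mass at one endpoint")
    peak = hist.max()
    values = hist / peak if peak > 0 else hist.astype(float)
    return FractionCurve(centers, values, com, degenerate)
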