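"""Polar growth asymmetry metrics.

Mycobacteria elongate from both poles at different rates: the old
(mother-inherited) pole incorporates new cell wall faster and over a broader
zone, so its axial fluorescence decay away from the tip is gentler.  This
module quantifies that per cell: a first-order polynomial is fitted to a
fixed number of profile points from each pole peak inward and its slope
magnitude is the decay measure; the pole/septum intensity ratio and
pole-aligned population averages summarize the incorporation pattern, and a
second reporter channel can be read out at each pole keyed by pole age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CellFlagged, ConfigurationError
from .landmarks import CellLandmarks
from .profiles import IntensityProfile, MeanProfile, average_profiles

__all__ = [
    "PoleMetrics",
    "AlignedPopulationProfile",
    "fit_pole_decay",
    "pole_septum_ratio",
    "aligned_mean_profile",
    "pole_channel_intensity",
    "slope_based_pole_age",
]

DEFAULT_K_POINTS = 10
SLOPE_AGE_AMBIGUITY = 0.10  # relative slope difference below which age is ambiguous


@dataclass
class PoleMetrics:
    """Per-cell pole decay slopes (magnitudes), fit quality, peak values,
    pole/septum intensity ratio, and pole-age labels."""

    cell_id: int
    slope_pole1: float
    r2_pole1: float
    slope_pole2: float
    r2_pole2: float
    pole1_value: float
    pole2_value: float
    pole_septum_ratio: float | None
    new_pole: str | None
    old_pole: str | None

    def slope(self, which: str) -> float:
        return self.slope_pole1 if which == "pole1" else self.slope_pole2

    @property
    def slope_new(self) -> float | None:
        if self.new_pole not in ("pole1", "pole2"):
            return None
        return self.slope(self.new_pole)

    @property
    def slope_old(self) -> float | None:
        if self.old_pole not in ("pole1", "pole2"):
            return None
        return self.slope(self.old_pole)


@dataclass
class AlignedPopulationProfile:
    """Population mean profile with the new pole at position 0."""

    profile: MeanProfile
    n_cells: int
    channel: str


def fit_pole_decay(profile: IntensityProfile, pole: str,
                   landmarks: CellLandmarks,
                   k_points: int = DEFAULT_K_POINTS) -> tuple[float, float]:
    """Slope magnitude and R^2 of the least-squares line through ``k_points``
    consecutive grid points from the pole peak toward midcell."""
    if pole not in ("pole1", "pole2"):
        raise ConfigurationError("pole must be 'pole1' or 'pole2'")
    pos = profile.positions
    vals = profile.values
    peak_pos = landmarks.pole_pos(pole)
    i0 = int(round(peak_pos / profile.step))
    if pole == "pole1":
        sel = slice(i0, i0 + k_points)
    else:
        sel = slice(max(i0 - k_points + 1, 0), i0 + 1)
    x = pos[sel]
    y = vals[sel]
    if len(x) < k_points:
        raise CellFlagged(profile.cell_id,
                          f"fewer than {k_points} points available from {pole}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return abs(float(slope)), r2


def pole_septum_ratio(landmarks: CellLandmarks) -> float:
    """(mean of both pole peak intensities) / septum peak intensity."""
    if landmarks.septum_value is None or landmarks.septum_value <= 0:
        raise CellFlagged(landmarks.cell_id,
                          "septum intensity absent or zero; ratio undefined")
    if landmarks.pole1_value <= 0 or landmarks.pole2_value <= 0:
        raise CellFlagged(landmarks.cell_id, "pole intensity not positive")
    return 0.5 * (landmarks.pole1_value + landmarks.pole2_value) / landmarks.septum_value


def aligned_mean_profile(profiles: list[IntensityProfile],
                         landmarks_list: list[CellLandmarks],
                         channel: str | None = None) -> AlignedPopulationProfile:
    """Average profiles after orienting each so the new pole sits at 0.

    Only septate cells with unambiguous pole-age labels are included."""
    if len(profiles) != len(landmarks_list):
        raise ConfigurationError("one landmark set per profile required")
    oriented = []
    for prof, lm in zip(profiles, landmarks_list):
        if lm.new_pole not in ("pole1", "pole2"):
            continue
        oriented.append(prof if lm.new_pole == "pole1" else prof.reversed())
    if not oriented:
        raise ConfigurationError("no septate, unambiguous cells to align")
    mean = average_profiles(oriented)
    name = channel or profiles[0].channel
    return AlignedPopulationProfile(mean, len(oriented), name)


def pole_channel_intensity(profile_ch2: IntensityProfile,
                           landmarks: CellLandmarks,
                           window: float = 0.05) -> dict[str, float]:
    """Mean second-channel intensity within +/-``window`` of each pole,
    keyed by pole age (``window=0`` reads the single nearest grid point)."""
    if landmarks.new_pole not in ("pole1", "pole2"):
        raise CellFlagged(landmarks.cell_id, "ambiguous pole-age labels")
    pos = profile_ch2.positions
    vals = profile_ch2.values
    out = {}
    for age, which in (("new", landmarks.new_pole), ("old", landmarks.old_pole)):
        center = landmarks.pole_pos(which)
        if window <= 0:
            out[age] = float(vals[int(np.argmin(np.abs(pos - center)))])
        else:
            sel = np.abs(pos - center) <= window + 1e-12
            out[age] = float(vals[sel].mean())
    return out


def slope_based_pole_age(metrics: PoleMetrics) -> tuple[str | None, str | None]:
    """Pole age from decay slopes alone: the gentler (smaller-magnitude)
    slope marks the old, faster-growing pole.  Slopes within
    ``SLOPE_AGE_AMBIGUITY`` relative difference are ambiguous.

    Returns ``(new_pole, old_pole)`` as 'pole1'/'pole2'/'ambiguous'."""
    s1, s2 = metrics.slope_pole1, metrics.slope_pole2
    denom = max(abs(s1), abs(s2))
    if denom == 0 or abs(s1 - s2) / denom < SLOPE_AGE_AMBIGUITY:
        return "ambiguous", "ambiguous"
    if s1 < s2:
        return "pole2", "pole1"   # pole1 gentler -> old
    return "pole1", "pole2"
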