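"""HADA foci detection and pole/septum landmark location on axial profiles.

Peak prominence is the selectivity knob.  Following the original protocol it
is calibrated on a control population — the value is chosen to maximize the
fraction of control cells in which exactly 2 (non-septate) or 3 (septate)
foci are found — and then frozen and applied unchanged to every comparison
group.  Profile endpoints are eligible as maxima so pole tips register as
foci.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import CalibrationError, ConfigurationError
from .profiles import IntensityProfile

__all__ = [
    "DetectedFocus",
    "FociSet",
    "CellLandmarks",
    "detect_foci",
    "calibrate_prominence",
    "interfoci_distances",
    "locate_landmarks",
    "classify_new_old",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEPARATION = 0.08
POLE_WINDOW = 0.15         # terminal fraction of length searched for pole peaks
SEPTUM_WINDOW = (0.15, 0.85)   # central 70% searched for the septum
AMBIGUITY_GRID_STEPS = 1.0     # new/old tie rule, in resampling steps


@dataclass(frozen=True)
class DetectedFocus:
    rel_pos: float
    value: float
    prominence: float


@dataclass
class FociSet:
    cell_id: int
    foci: list[DetectedFocus]

    def __post_init__(self):
        pos = [f.rel_pos for f in self.foci]
        if pos != sorted(pos):
            raise ConfigurationError("detected foci must be sorted by position")

    @property
    def count(self) -> int:
        return len(self.foci)

    @property
    def positions(self) -> np.ndarray:
        return np.array([f.rel_pos for f in self.foci])


@dataclass
class CellLandmarks:
    """Pole and septum positions/intensities, plus new/old pole labels.

    ``new_pole``/``old_pole`` are ``'pole1'``/``'pole2'`` references,
    ``'ambiguous'`` for a midcell tie, or ``None`` while unassigned or for
    non-septate cells.
    """

    cell_id: int
    pole1_pos: float
    pole2_pos: float
    pole1_value: float
    pole2_value: float
    septum_pos: float | None = None
    septum_value: float | None = None
    new_pole: str | None = None
    old_pole: str | None = None

    def __post_init__(self):
        if self.septum_pos is None and (self.new_pole or self.old_pole):
            raise ConfigurationError("pole-age labels require a septum")

    @property
    def septate(self) -> bool:
        return self.septum_pos is not None

    @property
    def septum_rel_pos(self) -> float | None:
        """Distance from the septum to the nearest pole as a length fraction,
        in (0, 0.5]; 0.5 means midcell."""
        if self.septum_pos is None:
            return None
        return min(self.septum_pos, 1.0 - self.septum_pos)

    def pole_pos(self, which: str) -> float:
        return self.pole1_pos if which == "pole1" else self.pole2_pos

    def pole_value(self, which: str) -> float:
        return self.pole1_value if which == "pole1" else self.pole2_value


# ---------------------------------------------------------------------------

def _peaks_with_endpoints(values: np.ndarray, prominence: float,
                          distance_samples: int):
    """find_peaks with the profile endpoints eligible as maxima.

    The trace is padded with one sample at the global minimum on each side so
    an endpoint higher than its neighbor forms a proper local maximum; indices
    are shifted back afterwards.
    """
    pad = float(values.min())
    padded = np.concatenate([[pad], values, [pad]])
    idx, props = find_peaks(padded, prominence=prominence,
                            distance=max(distance_samples, 1))
    idx = idx - 1
    keep = (idx >= 0) & (idx < len(values))
    return idx[keep], props["prominences"][keep]


def detect_foci(profile: IntensityProfile, prominence: float,
                min_separation: float = DEFAULT_MIN_SEPARATION) -> FociSet:
    """All local maxima with prominence >= threshold and pairwise separation
    >= ``min_separation`` (fraction of normalized length)."""
    if prominence <= 0:
        raise ConfigurationError("prominence must be > 0")
    if not 0.0 <= min_separation < 0.5:
        raise ConfigurationError("min_separation must lie in [0, 0.5)")
    step = profile.step
    dist = int(round(min_separation / step))
    idx, proms = _peaks_with_endpoints(profile.values, prominence, dist)
    foci = [DetectedFocus(float(profile.positions[i]),
                          float(profile.values[i]), float(p))
            for i, p in zip(idx, proms)]
    foci.sort(key=lambda f: f.rel_pos)
    return FociSet(profile.cell_id, foci)


def calibrate_prominence(control_profiles: list[IntensityProfile],
                         septate_flags: list[bool],
                         min_separation: float = DEFAULT_MIN_SEPARATION,
                         grid_size: int = 30,
                         grid_range: tuple[float, float] = (0.02, 1.0),
                         min_agreement: float = 0.5):
    """Choose the prominence that maximizes 2-foci (non-septate) / 3-foci
    (septate) agreement on a control population, then freeze it.

    The search grid is ``grid_size`` log-spaced multiples of the control
    population's median peak value, spanning ``grid_range``.  Returns
    ``(prominence, diagnostics)``; raises :class:`CalibrationError` if no
    value reaches ``min_agreement``.
    """
    if len(control_profiles) < 20:
        raise CalibrationError(
            f"need >= 20 control cells to calibrate, got {len(control_profiles)}"
        )
    if len(control_profiles) != len(septate_flags):
        raise ConfigurationError("one septation flag per control profile required")
    median_peak = float(np.median([p.values.max() for p in control_profiles]))
    if median_peak <= 0:
        raise CalibrationError("control profiles carry no signal")
    grid = median_peak * np.geomspace(grid_range[0], grid_range[1], grid_size)
    expected = np.where(np.asarray(septate_flags, bool), 3, 2)
    agreement = np.empty(grid_size)
    for g, prom in enumerate(grid):
        counts = np.array([
            detect_foci(p, prom, min_separation).count for p in control_profiles
        ])
        agreement[g] = float(np.mean(counts == expected))
    best = agreement.max()
    if best < min_agreement:
        raise CalibrationError(
            f"best count agreement {best:.2f} < {min_agreement:.2f}: "
            "control population unusable for calibration"
        )
    # middle of the maximizing plateau, for stability on either side
    winners = np.flatnonzero(agreement == best)
    pick = int(winners[len(winners) // 2])
    diagnostics = {
        "grid": grid.tolist(),
        "agreement": agreement.tolist(),
        "median_peak": median_peak,
        "best_agreement": float(best),
        "chosen_index": pick,
        "n_control": len(control_profiles),
    }
    return float(grid[pick]), diagnostics


def interfoci_distances(foci: FociSet) -> list[float]:
    """Consecutive distances between foci as fractions of cell length.

    Fewer than two foci yields an empty list (the cell contributes nothing
    to the distance distribution)."""
    if foci.count < 2:
        logger.debug("cell %s: <2 foci, no inter-foci distances", foci.cell_id)
        return []
    return list(np.diff(foci.positions))


def locate_landmarks(profile: IntensityProfile, prominence: float,
                     septate_expected: bool | None = None,
                     min_separation: float = DEFAULT_MIN_SEPARATION) -> CellLandmarks:
    """Locate pole peaks and, if present, the septum on one profile.

    Pole peaks are the highest local maxima within the terminal
    ``POLE_WINDOW`` fraction at each end (falling back to the endpoint
    values); the septum is the highest qualifying interior local maximum in
    the central 70%.  ``septate_expected=False`` suppresses the septum
    search; ``None`` infers septation from the presence of a qualifying
    interior peak.
    """
    vals = profile.values
    pos = profile.positions
    step = profile.step
    idx, proms = _peaks_with_endpoints(vals, prominence,
                                       int(round(min_separation / step)))

    def pole_peak(window_lo, window_hi, fallback_idx):
        cand = [i for i in idx if window_lo <= pos[i] <= window_hi]
        if not cand:
            return fallback_idx
        return max(cand, key=lambda i: vals[i])

    i1 = pole_peak(0.0, POLE_WINDOW, 0)
    i2 = pole_peak(1.0 - POLE_WINDOW, 1.0, len(vals) - 1)

    septum_pos = septum_value = None
    if septate_expected is not False:
        interior = [(i, p) for i, p in zip(idx, proms)
                    if SEPTUM_WINDOW[0] <= pos[i] <= SEPTUM_WINDOW[1]]
        if interior:
            best_i, best_p = max(interior, key=lambda t: vals[t[0]])
            near = [(i, p) for i, p in interior
                    if abs(pos[i] - pos[best_i]) <= 0.05 and i != best_i]
            if near:
                contender_i, contender_p = max(near, key=lambda t: t[1])
                if contender_p > best_p:
                    logger.debug("cell %s: septum tie at %.2f vs %.2f, "
                                 "keeping the more prominent",
                                 profile.cell_id, pos[best_i], pos[contender_i])
                    best_i = contender_i
            septum_pos = float(pos[best_i])
            septum_value = float(vals[best_i])
        elif septate_expected is True:
            logger.debug("cell %s: expected septum not found", profile.cell_id)

    return CellLandmarks(
        cell_id=profile.cell_id,
        pole1_pos=float(pos[i1]),
        pole2_pos=float(pos[i2]),
        pole1_value=float(vals[i1]),
        pole2_value=float(vals[i2]),
        septum_pos=septum_pos,
        septum_value=septum_value,
    )


def classify_new_old(landmarks: CellLandmarks,
                     grid_step: float = 0.01) -> CellLandmarks:
    """Label the pole nearer the septum as new, the other as old.

    Equidistant poles (within one grid step) are labeled ``'ambiguous'`` and
    excluded from pole-aligned statistics downstream.  Non-septate input is
    returned unchanged (labels stay absent).
    """
    if landmarks.septum_pos is None:
        return landmarks
    d1 = abs(landmarks.septum_pos - landmarks.pole1_pos)
    d2 = abs(landmarks.septum_pos - landmarks.pole2_pos)
    if abs(d1 - d2) < AMBIGUITY_GRID_STEPS * grid_step:
        new = old = "ambiguous"
    elif d1 < d2:
        new, old = "pole1", "pole2"
    else:
        new, old = "pole2", "pole1"
    return dataclasses.replace(landmarks, new_pole=new, old_pole=old)
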