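"""In-memory orchestration: scenes -> profiles -> landmarks -> metrics.

These helpers keep the per-cell bookkeeping (unique cell ids across scenes,
exclusion reasons) in one place; the file-based pipeline and the test suite
both run through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import asymmetry as asy
from . import landmarks as lmk
from . import profiles as prf
from .errors import CellFlagged
from .synthgen import GroundTruth, ImageScene

__all__ = ["PopulationProfiles", "extract_population_profiles",
           "analyze_population", "metrics_table"]

logger = logging.getLogger(__name__)


@dataclass
class PopulationProfiles:
    """Profiles of one channel for a whole population, keyed by global cell id."""

    profiles: dict[int, prf.IntensityProfile]
    excluded: dict[int, str] = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return len(self.profiles) + len(self.excluded)


def extract_population_profiles(scenes: list[ImageScene], channel: str,
                                ground_truth: GroundTruth | None = None,
                                width_px: int = prf.DEFAULT_WIDTH_PX,
                                resample_points: int = prf.DEFAULT_RESAMPLE_POINTS,
                                mask_aware: bool = True) -> PopulationProfiles:
    """Extract one profile per labeled cell across scenes.

    Global cell ids come from the ground truth when available (mapping
    scene index + label back to the generator's cell id), else from a
    running counter."""
    id_map = {}
    if ground_truth is not None:
        for rec in ground_truth.records:
            id_map[(rec.scene_index, rec.label)] = rec.spec.cell_id
    profiles: dict[int, prf.IntensityProfile] = {}
    excluded: dict[int, str] = {}
    counter = 0
    for s_idx, scene in enumerate(scenes):
        got, exc = prf.profile_scene(scene, channel, width_px=width_px,
                                     resample_points=resample_points,
                                     mask_aware=mask_aware)
        for label in sorted(set(got) | set(exc)):
            counter += 1
            cid = id_map.get((s_idx, label), counter)
            if label in got:
                p = got[label]
                p.cell_id = cid
                profiles[cid] = p
            else:
                excluded[cid] = exc[label]
                logger.info("cell %s excluded: %s", cid, exc[label])
    return PopulationProfiles(profiles, excluded)


def analyze_population(pop: PopulationProfiles, prominence: float,
                       min_separation: float = lmk.DEFAULT_MIN_SEPARATION,
                       septate_by_cell: dict[int, bool] | None = None,
                       ch2: PopulationProfiles | None = None):
    """Landmarks, foci and asymmetry metrics for every profiled cell.

    Returns ``(landmarks, foci_sets, metrics_df, excluded)``."""
    landmarks: dict[int, lmk.CellLandmarks] = {}
    foci_sets: dict[int, lmk.FociSet] = {}
    excluded: dict[int, str] = {}
    rows = []
    for cid, prof in pop.profiles.items():
        expected = septate_by_cell.get(cid) if septate_by_cell else None
        lm = lmk.locate_landmarks(prof, prominence, septate_expected=expected,
                                  min_separation=min_separation)
        lm = lmk.classify_new_old(lm, grid_step=prof.step)
        fs = lmk.detect_foci(prof, prominence, min_separation)
        landmarks[cid] = lm
        foci_sets[cid] = fs

        row = {
            "cell_id": cid,
            "length_um": prof.length_um,
            "foci_count": fs.count,
            "septate": lm.septate,
            "septum_rel_pos": lm.septum_rel_pos,
            "new_pole": lm.new_pole,
            "old_pole": lm.old_pole,
        }
        try:
            s1, r1 = asy.fit_pole_decay(prof, "pole1", lm)
            s2, r2 = asy.fit_pole_decay(prof, "pole2", lm)
        except CellFlagged as exc:
            excluded[cid] = exc.reason
            continue
        metrics = asy.PoleMetrics(
            cell_id=cid, slope_pole1=s1, r2_pole1=r1, slope_pole2=s2,
            r2_pole2=r2, pole1_value=lm.pole1_value,
            pole2_value=lm.pole2_value, pole_septum_ratio=None,
            new_pole=lm.new_pole, old_pole=lm.old_pole,
        )
        if lm.septate:
            try:
                metrics.pole_septum_ratio = asy.pole_septum_ratio(lm)
            except CellFlagged as exc:
                logger.info("%s", exc)
        row.update({
            "slope_pole1": s1, "r2_pole1": r1,
            "slope_pole2": s2, "r2_pole2": r2,
            "slope_new": metrics.slope_new, "slope_old": metrics.slope_old,
            "pole_septum_ratio": metrics.pole_septum_ratio,
        })
        dists = lmk.interfoci_distances(fs)
        row["mean_interfoci_distance"] = float(np.mean(dists)) if dists else np.nan
        if ch2 is not None and cid in ch2.profiles and lm.new_pole in ("pole1", "pole2"):
            try:
                by_age = asy.pole_channel_intensity(ch2.profiles[cid], lm)
                row["ch2_old_pole"] = by_age["old"]
                row["ch2_new_pole"] = by_age["new"]
            except CellFlagged:
                pass
        rows.append(row)
    return landmarks, foci_sets, pd.DataFrame(rows), excluded


def metrics_table(populations: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-group metric tables with a ``group`` column."""
    frames = []
    for name, df in populations.items():
        df = df.copy()
        df.insert(0, "group", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
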