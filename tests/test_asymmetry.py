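"""Pole decay slopes, ratios, alignment, and pole-age classification."""

import numpy as np
import pytest

from poleprof import asymmetry as asy
from poleprof import landmarks as lmk
from poleprof import synthgen, workflow
from poleprof.errors import CellFlagged

from conftest import gaussian_bump, make_profile


def _lm(pole1=0.0, pole2=1.0, v1=80.0, v2=75.0, septum=None, vs=None,
        new=None, old=None):
    return lmk.CellLandmarks(1, pole1, pole2, v1, v2, septum_pos=septum,
                             septum_value=vs, new_pole=new, old_pole=old)


def test_exact_linear_segment_slope():
    x = np.linspace(0, 1, 101)
    p = make_profile(np.clip(1 - 2 * x, 0, None))
    slope, r2 = asy.fit_pole_decay(p, "pole1", _lm())
    assert slope == pytest.approx(2.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_constant_segment_slope_zero():
    p = make_profile(np.full(101, 5.0))
    slope, r2 = asy.fit_pole_decay(p, "pole1", _lm())
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_noisy_segment_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        vals = rng.random(101) * 10
        p = make_profile(vals)
        slope, _ = asy.fit_pole_decay(p, "pole2", _lm())
        x = p.positions[-10:]
        y = vals[-10:]
        n = len(x)
        beta = ((n * (x * y).sum() - x.sum() * y.sum())
                / (n * (x * x).sum() - x.sum() ** 2))
        assert slope == pytest.approx(abs(beta), abs=1e-10)


def test_too_few_points_raises():
    p = make_profile(np.arange(5, dtype=float))
    with pytest.raises(CellFlagged):
        asy.fit_pole_decay(p, "pole1", _lm(), k_points=10)


def test_pole_septum_ratio_examples():
    assert asy.pole_septum_ratio(_lm(v1=2.0, v2=2.0, septum=0.5, vs=1.0)) == 2.0
    assert asy.pole_septum_ratio(_lm(v1=1.0, v2=1.0, septum=0.5, vs=1.0)) == 1.0
    with pytest.raises(CellFlagged):
        asy.pole_septum_ratio(_lm())  # no septum


def test_ratio_scale_invariance():
    lm_a = _lm(v1=3.0, v2=2.0, septum=0.4, vs=1.5)
    lm_b = _lm(v1=30.0, v2=20.0, septum=0.4, vs=15.0)
    assert asy.pole_septum_ratio(lm_a) == pytest.approx(asy.pole_septum_ratio(lm_b))


def test_preset_ratio_phenotypes():
    """Polar incorporation dominates in the control strain (ratio > 1);
    septal incorporation dominates in the knockout (ratio < 1)."""
    ratios = {}
    prom = None
    for preset in ("control", "delta_fhaA"):
        scenes, gt = synthgen.generate_population(preset, 30, seed=17)
        pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
        if prom is None:
            flags = [gt[c].septate for c in pop.profiles]
            prom, _ = lmk.calibrate_prominence(list(pop.profiles.values()), flags)
        _, _, df, _ = workflow.analyze_population(pop, prom)
        ratios[preset] = df["pole_septum_ratio"].median(skipna=True)
    assert ratios["control"] > 1.0
    assert ratios["delta_fhaA"] < 1.0


# --- alignment -------------------------------------------------------------

def test_aligned_single_cell_orientation():
    vals = gaussian_bump(0.4, 60.0) + gaussian_bump(0.0, 80.0, 0.05)
    p = make_profile(vals)
    lm = _lm(septum=0.4, vs=60.0, new="pole1", old="pole2")
    out = asy.aligned_mean_profile([p], [lm])
    assert np.allclose(out.profile.mean, p.values)
    lm_rev = _lm(septum=0.6, vs=60.0, new="pole2", old="pole1")
    out_rev = asy.aligned_mean_profile([p.reversed()], [lm_rev])
    assert np.allclose(out_rev.profile.mean, p.values)


def test_aligned_population_slope_ordering(control_snr10):
    """The aligned mean profile decays more steeply at the new pole (pos 0)
    than at the old pole (pos 1)."""
    _, gt, pop, prom = control_snr10
    profs, lms = [], []
    for cid, p in pop.profiles.items():
        lm = lmk.classify_new_old(lmk.locate_landmarks(p, prom), p.step)
        if lm.new_pole in ("pole1", "pole2"):
            profs.append(p)
            lms.append(lm)
    out = asy.aligned_mean_profile(profs, lms)
    mean_prof = make_profile(out.profile.mean)
    s_new, _ = asy.fit_pole_decay(mean_prof, "pole1", _lm())
    s_old, _ = asy.fit_pole_decay(mean_prof, "pole2", _lm())
    assert s_new > s_old


def test_pole_channel_intensity_uniform_and_window_zero():
    uniform = make_profile(np.full(101, 4.0), channel="mscarlet")
    lm = _lm(septum=0.4, vs=1.0, new="pole1", old="pole2")
    out = asy.pole_channel_intensity(uniform, lm)
    assert out["old"] == out["new"] == pytest.approx(4.0)
    ramp = make_profile(np.linspace(0, 1, 101), channel="mscarlet")
    out0 = asy.pole_channel_intensity(ramp, lm, window=0.0)
    assert out0["new"] == pytest.approx(0.0)
    assert out0["old"] == pytest.approx(1.0)


def test_pole_channel_ratio_matches_generator_weights():
    """Old-pole-weighted reporter: windowed means reproduce the generator's
    per-pole weight ratio within 10% (noiseless)."""
    scenes, gt = synthgen.generate_population(
        "control", 20, seed=23,
        overrides={"noise": False, "septate_fraction": 1.0})
    pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
    ch2 = workflow.extract_population_profiles(scenes, "mscarlet", ground_truth=gt)
    w_ratio = (synthgen.PRESETS["control"]["channel2_old_weight"]
               / synthgen.PRESETS["control"]["channel2_new_weight"])
    flags = [gt[c].septate for c in pop.profiles]
    prom, _ = lmk.calibrate_prominence(list(pop.profiles.values()), flags,
                                       min_agreement=0.4)
    checked = 0
    for cid, p in pop.profiles.items():
        lm = lmk.classify_new_old(lmk.locate_landmarks(p, prom), p.step)
        if lm.new_pole not in ("pole1", "pole2"):
            continue
        out = asy.pole_channel_intensity(ch2.profiles[cid], lm)
        assert out["old"] / out["new"] == pytest.approx(w_ratio, rel=0.10)
        checked += 1
    assert checked >= 8


def test_ambiguous_pole_labels_excluded():
    p = make_profile(np.full(101, 4.0))
    lm = _lm(septum=0.5, vs=1.0, new="ambiguous", old="ambiguous")
    with pytest.raises(CellFlagged):
        asy.pole_channel_intensity(p, lm)


# --- slope-based pole age --------------------------------------------------

def _metrics(s1, s2):
    return asy.PoleMetrics(1, s1, 1.0, s2, 1.0, 0, 0, None, None, None)


def test_slope_age_rules():
    new, old = asy.slope_based_pole_age(_metrics(1.0, 3.0))
    assert old == "pole1" and new == "pole2"
    assert asy.slope_based_pole_age(_metrics(2.0, 2.05)) == ("ambiguous",
                                                             "ambiguous")


def test_equal_extent_preset_has_symmetric_slopes():
    """With equal per-pole decay extents the paired slope difference is
    centered on zero (sign test, noiseless)."""
    from scipy import stats
    scenes, gt = synthgen.generate_population(
        "delta_fhaA", 60, seed=37, overrides={"noise": False})
    pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
    flags = [gt[c].septate for c in pop.profiles]
    prom, _ = lmk.calibrate_prominence(list(pop.profiles.values()), flags)
    _, _, df, _ = workflow.analyze_population(pop, prom)
    diff = (df["slope_pole1"] - df["slope_pole2"]).to_numpy()
    n_pos = int((diff > 0).sum())
    p = stats.binomtest(n_pos, len(diff), 0.5).pvalue
    assert p > 0.01


def test_reversal_invariance_of_cell_metrics(control_noiseless):
    _, gt, pop = control_noiseless
    for cid, p in list(pop.profiles.items())[:6]:
        lm = lmk.locate_landmarks(p, 10.0)
        rp = p.reversed()
        rlm = lmk.locate_landmarks(rp, 10.0)
        s1, _ = asy.fit_pole_decay(p, "pole1", lm)
        s2r, _ = asy.fit_pole_decay(rp, "pole2", rlm)
        assert s1 == pytest.approx(s2r, rel=1e-9, abs=1e-9)
        if lm.septate and rlm.septate:
            assert lm.septum_rel_pos == pytest.approx(rlm.septum_rel_pos,
                                                      abs=1e-9)
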