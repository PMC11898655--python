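"""Medial axis, length, and profile extraction contracts."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from poleprof import profiles as prf
from poleprof import synthgen
from poleprof.errors import CellFlagged, ConfigurationError

from conftest import capsule_mask, make_profile


# --- medial axis -----------------------------------------------------------

def test_straight_capsule_axis_length():
    """A horizontal capsule 100 px end-to-end yields a 100 +/- 1 px axis."""
    # tips at columns 12 and 111: the mask spans 100 pixel columns
    mask = capsule_mask((40, 130), (20.0, 12.0), (20.0, 111.0), width=8.0)
    labels = mask.astype(np.uint16)
    axis = prf.extract_medial_axis(labels, 1, pixel_size_um=0.105)
    assert axis.length_px == pytest.approx(100.0, abs=1.0)
    assert prf.measure_length(axis) == pytest.approx(10.5, abs=0.105)


def test_disk_region_is_flagged():
    rr, cc = np.mgrid[0:40, 0:40]
    labels = ((rr - 20) ** 2 + (cc - 20) ** 2 <= 12 ** 2).astype(np.uint16)
    with pytest.raises(CellFlagged):
        prf.extract_medial_axis(labels, 1, pixel_size_um=0.105)


def test_missing_label_is_flagged():
    with pytest.raises(CellFlagged):
        prf.extract_medial_axis(np.zeros((10, 10), np.uint16), 3, 0.105)


def test_curved_cell_axis_within_one_px_of_truth(control_noiseless):
    scenes, gt, _ = control_noiseless
    for rec in gt.records[:15]:
        scene = scenes[rec.scene_index]
        axis = prf.extract_medial_axis(scene.labels, rec.label,
                                       scene.pixel_size_um)
        t_true = cKDTree(rec.centerline_px)
        t_est = cKDTree(axis.points)
        hausdorff = max(t_true.query(axis.points)[0].max(),
                        t_est.query(rec.centerline_px)[0].max())
        assert hausdorff <= 1.0 + 0.25  # resampling step slack


def test_population_length_recovery(control_noiseless):
    """Mean absolute length error <= 2% of truth on noiseless cells."""
    _, gt, pop = control_noiseless
    errs = [abs(p.length_um - gt[c].length_um) / gt[c].length_um
            for c, p in pop.profiles.items()]
    assert np.mean(errs) <= 0.02


def test_axis_orientation_deterministic(control_noiseless):
    scenes, gt, _ = control_noiseless
    scene = scenes[0]
    a = prf.extract_medial_axis(scene.labels, 1, scene.pixel_size_um)
    b = prf.extract_medial_axis(scene.labels, 1, scene.pixel_size_um)
    assert np.array_equal(a.points, b.points)
    assert tuple(a.points[0]) < tuple(a.points[-1])


def test_zero_length_axis_rejected():
    with pytest.raises(ConfigurationError):
        prf.MedialAxis(1, np.array([[0.0, 0.0]]), np.array([0.0]), 0.105)


# --- profile extraction ----------------------------------------------------

def _horizontal_axis(length_px, row, col0, pixel_size=0.105):
    pts = np.stack([np.full(200, float(row)),
                    np.linspace(col0, col0 + length_px, 200)], axis=1)
    return prf.axis_from_points(pts, pixel_size)


def test_uniform_channel_gives_constant_profile():
    channel = np.full((40, 130), 7.5)
    axis = _horizontal_axis(100, 20, 12)
    p = prf.extract_profile(channel, axis, background=2.5)
    assert np.allclose(p.values, 5.0, atol=1e-6)
    assert p.positions[0] == 0.0 and p.positions[-1] == 1.0


def test_all_zero_channel_gives_flat_zero_profile():
    axis = _horizontal_axis(60, 20, 12)
    p = prf.extract_profile(np.zeros((40, 90)), axis)
    assert np.all(p.values == 0.0)


def test_noiseless_focus_argmax_at_true_position(control_noiseless):
    scenes, gt, pop = control_noiseless
    for cid, p in list(pop.profiles.items())[:10]:
        rec = gt[cid]
        if not rec.septate:
            continue
        # septum is the only interior peak; check argmax of the interior
        interior = slice(20, 81)
        i = int(np.argmax(p.values[interior])) + 20
        assert abs(p.positions[i] - rec.septum_rel_pos) <= 0.02


def test_band_average_matches_bruteforce_bilinear_oracle():
    """Off-axis focus: extraction equals a hand-written per-station bilinear
    averaging loop to 1e-9, and an on-axis focus yields a peak at least as
    high as the same focus displaced 3 px off-axis."""
    shape = (41, 120)
    row_axis = 20.0

    def blob_image(row_c, col_c, amp=100.0, sigma=2.0):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return amp * np.exp(-((rr - row_c) ** 2 + (cc - col_c) ** 2)
                            / (2 * sigma ** 2))

    axis = _horizontal_axis(100, row_axis, 10)

    def oracle(channel, width_px, resample_points=101):
        total = axis.length_px
        stations = np.linspace(0.0, total, int(np.ceil(total)) + 1)
        band = []
        for s in stations:
            vals = []
            for k in range(width_px):
                off = k - (width_px - 1) / 2.0
                r, c = row_axis + off, 10.0 + s  # perpendicular is vertical
                r0, c0 = int(np.floor(r)), int(np.floor(c))
                fr, fc = r - r0, c - c0
                v = (channel[r0, c0] * (1 - fr) * (1 - fc)
                     + channel[r0 + 1, c0] * fr * (1 - fc)
                     + channel[r0, c0 + 1] * (1 - fr) * fc
                     + channel[r0 + 1, c0 + 1] * fr * fc)
                vals.append(v)
            band.append(np.mean(vals))
        grid = np.linspace(0, 1, resample_points)
        from scipy.interpolate import make_interp_spline
        return np.clip(make_interp_spline(stations, band, k=3)(grid * total),
                       0, None)

    on_axis = blob_image(row_axis, 60.0)
    off_axis = blob_image(row_axis + 3.0, 60.0)
    for img in (on_axis, off_axis):
        p = prf.extract_profile(img, axis, width_px=10, interp_order=1)
        assert np.max(np.abs(p.values - oracle(img, 10))) < 1e-9
    p_on = prf.extract_profile(on_axis, axis, width_px=10, interp_order=1)
    p_off = prf.extract_profile(off_axis, axis, width_px=10, interp_order=1)
    assert p_on.values.max() >= p_off.values.max()


def test_reversal_equivariance(control_noiseless):
    scenes, gt, _ = control_noiseless
    rec = gt.records[0]
    scene = scenes[rec.scene_index]
    axis = prf.extract_medial_axis(scene.labels, rec.label, scene.pixel_size_um)
    ch = scene.channels["hada"]
    wm = scene.labels == rec.label
    fwd = prf.extract_profile(ch, axis, weight_mask=wm)
    rev = prf.extract_profile(ch, axis.reversed(), weight_mask=wm)
    assert np.max(np.abs(fwd.values - rev.values[::-1])) <= 1e-9


def test_width_monotonicity_peak_dilution():
    """For a transversely centered signal, widening the band never raises
    the peak value."""
    shape = (41, 120)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = 100.0 * np.exp(-((rr - 20) ** 2 + (cc - 60) ** 2) / (2 * 2.0 ** 2))
    axis = _horizontal_axis(100, 20, 10)
    peaks = [prf.extract_profile(img, axis, width_px=w).values.max()
             for w in (1, 3, 5, 10)]
    assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))


def test_render_extract_roundtrip_matches_analytic_profile():
    """Noiseless PSF-free rendering re-extracted along the true centerline
    reproduces the generator's analytic axial profile to <= 2% of peak."""
    scenes, gt = synthgen.generate_population(
        "control", 25, seed=2, overrides={"noise": False, "psf_sigma_px": 0.0})
    for scene, rec in zip(scenes, gt.records):
        axis = prf.axis_from_points(rec.centerline_px, scene.pixel_size_um,
                                    rec.spec.cell_id)
        ch = scene.channels["hada"]
        bg = prf.estimate_background(ch, scene.labels)
        p = prf.extract_profile(ch, axis, background=bg,
                                weight_mask=scene.labels == rec.label)
        analytic = synthgen.axial_intensity(rec.spec, p.positions)
        assert np.max(np.abs(p.values - analytic)) <= 0.02 * analytic.max()


# --- averaging -------------------------------------------------------------

def test_average_identical_profiles():
    p = make_profile(np.linspace(1, 3, 101))
    m = prf.average_profiles([p, p, p])
    assert np.allclose(m.mean, p.values)
    assert np.allclose(m.sd, 0.0)
    assert m.n_cells == 3


def test_average_two_profiles_sample_sd():
    a = make_profile(np.zeros(11))
    b = make_profile(np.full(11, 2.0))
    m = prf.average_profiles([a, b])
    assert np.allclose(m.mean, 1.0)
    assert np.allclose(m.sd, np.sqrt(2.0))  # sample SD, n-1 denominator


def test_average_rejects_empty_and_mixed_grids():
    with pytest.raises(ConfigurationError):
        prf.average_profiles([])
    with pytest.raises(ConfigurationError):
        prf.average_profiles([make_profile(np.zeros(11)),
                              make_profile(np.zeros(21))])


def test_septate_mean_profile_has_three_peaks(control_noiseless):
    """Averaging septate control cells leaves exactly 3 prominent maxima
    (two poles and the septum)."""
    from scipy.signal import find_peaks
    _, gt, pop = control_noiseless
    septate = [p for c, p in pop.profiles.items() if gt[c].septate]
    m = prf.average_profiles(septate)
    padded = np.concatenate([[m.mean.min()], m.mean, [m.mean.min()]])
    peaks, _ = find_peaks(padded, prominence=0.15 * m.mean.max())
    assert len(peaks) == 3


def test_segment_otsu_labels_synthetic_cells(control_snr10):
    scenes, _, _, _ = control_snr10
    labels = prf.segment_otsu(scenes[0].channels["membrane"])
    assert labels.max() >= 1
    got = labels > 0
    want = scenes[0].labels > 0
    overlap = (got & want).sum() / want.sum()
    assert overlap > 0.8
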