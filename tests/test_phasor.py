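"""Spectral phasor transform: oracles, invariants, fractions, curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poleprof import phasor as phs
from poleprof import synthgen
from poleprof.errors import ConfigurationError


def _scene_from_spectra(spectra):
    """Wrap an (N, K) spectrum list into a 1 x N x K SpectralScene."""
    spectra = np.asarray(spectra, dtype=float)
    stack = spectra[None, :, :]
    wl = 423.0 + 10.0 * np.arange(spectra.shape[1])
    labels = np.ones(stack.shape[:2], dtype=np.uint16)
    return synthgen.SpectralScene(stack, wl, labels, 0.05, 0)


def direct_phasor(spectrum, harmonic=1):
    """Independent brute-force trig summation oracle."""
    K = len(spectrum)
    g = s = tot = 0.0
    for k, I in enumerate(spectrum):
        g += I * np.cos(2 * np.pi * harmonic * k / K)
        s += I * np.sin(2 * np.pi * harmonic * k / K)
        tot += I
    return g / tot, s / tot


def test_uniform_spectrum_maps_to_origin():
    scene = _scene_from_spectra([np.ones(30)])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    assert abs(f.G[0, 0]) < 1e-12 and abs(f.S[0, 0]) < 1e-12


def test_delta_spectrum_on_unit_circle():
    spec = np.zeros(30)
    spec[0] = 5.0
    scene = _scene_from_spectra([spec])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    assert f.G[0, 0] == pytest.approx(1.0, abs=1e-12)
    assert f.S[0, 0] == pytest.approx(0.0, abs=1e-12)
    assert f.M[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_gaussian_spectrum_matches_trig_oracle():
    wl = 423.0 + 10.0 * np.arange(30)
    spec = np.exp(-0.5 * ((wl - 490.0) / 25.0) ** 2)
    scene = _scene_from_spectra([spec])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    g, s = direct_phasor(spec)
    assert f.G[0, 0] == pytest.approx(g, abs=1e-12)
    assert f.S[0, 0] == pytest.approx(s, abs=1e-12)


def test_matches_generic_dft_first_harmonic():
    rng = np.random.default_rng(5)
    spectra = rng.random((64, 30))
    scene = _scene_from_spectra(spectra)
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    F = np.fft.fft(spectra, axis=1)
    tot = spectra.sum(axis=1)
    assert np.max(np.abs(f.G[0] - F[:, 1].real / tot)) < 1e-10
    assert np.max(np.abs(f.S[0] + F[:, 1].imag / tot)) < 1e-10


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1e6), min_size=4, max_size=40).filter(
    lambda xs: sum(xs) > 0))
def test_modulus_bounded_by_unit_circle(spectrum):
    g, s = direct_phasor(np.array(spectrum))
    p = phs.phasor_of_spectrum(np.array(spectrum))
    assert p.M <= 1.0 + 1e-12
    assert p.G == pytest.approx(g, abs=1e-9)


def test_scale_invariance():
    rng = np.random.default_rng(11)
    spec = rng.random(30)
    a = phs.phasor_of_spectrum(spec)
    b = phs.phasor_of_spectrum(1e4 * spec)
    assert a.G == pytest.approx(b.G, abs=1e-12)
    assert a.S == pytest.approx(b.S, abs=1e-12)


def test_linearity_intensity_weighted_mean():
    rng = np.random.default_rng(13)
    for _ in range(30):
        A, B = rng.random(30) * 10, rng.random(30) * 10
        pA, pB = phs.phasor_of_spectrum(A), phs.phasor_of_spectrum(B)
        pSum = phs.phasor_of_spectrum(A + B)
        wa, wb = A.sum(), B.sum()
        assert pSum.G == pytest.approx((wa * pA.G + wb * pB.G) / (wa + wb),
                                       abs=1e-12)
        assert pSum.S == pytest.approx((wa * pA.S + wb * pB.S) / (wa + wb),
                                       abs=1e-12)


def test_negative_intensity_rejected():
    stack = -np.ones((2, 2, 30))
    scene = synthgen.SpectralScene(np.abs(stack), 423 + 10.0 * np.arange(30),
                                   np.ones((2, 2), np.uint16), 0.05, 0)
    scene.stack = stack  # corrupt after validation
    with pytest.raises(ConfigurationError):
        phs.spectral_phasor(scene)


# --- summaries -------------------------------------------------------------

def test_summary_of_identical_phasors():
    spec = np.zeros(30)
    spec[3] = 2.0
    scene = _scene_from_spectra([spec] * 8)
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    s = phs.phasor_summary(f)[0]
    expected = phs.phasor_of_spectrum(spec)
    assert s["mean_G"] == pytest.approx(expected.G, abs=1e-12)
    assert s["dispersion"] == pytest.approx(0.0, abs=1e-12)


def test_summary_midpoint_of_two_equal_sets():
    d1, d2 = np.zeros(30), np.zeros(30)
    d1[0] = 1.0
    d2[7] = 1.0
    scene = _scene_from_spectra([d1] * 4 + [d2] * 4)
    s = phs.phasor_summary(phs.spectral_phasor(scene, intensity_threshold=0.0))[0]
    p1, p2 = phs.phasor_of_spectrum(d1), phs.phasor_of_spectrum(d2)
    assert s["mean_G"] == pytest.approx((p1.G + p2.G) / 2, abs=1e-12)
    assert s["mean_S"] == pytest.approx((p1.S + p2.S) / 2, abs=1e-12)


def test_red_shift_rotates_phasor_counterclockwise(spectral_pair):
    """The +30 nm (red-shifted) preset has a larger mean phase angle."""
    control, shifted = spectral_pair
    phi_c = phs.phasor_summary(phs.spectral_phasor(control))[0]["mean_Phi"]
    phi_s = phs.phasor_summary(phs.spectral_phasor(shifted))[0]["mean_Phi"]
    assert phi_s > phi_c
    # blue shift goes the other way (clockwise)
    blue, _ = synthgen.generate_spectral_population(
        "shifted", 3, seed=33, overrides={"center_nm": 460.0})
    phi_b = phs.phasor_summary(phs.spectral_phasor(blue))[0]["mean_Phi"]
    assert phi_b < phi_c


# --- linear fractions ------------------------------------------------------

def _refs():
    wl = 423.0 + 10.0 * np.arange(30)
    A = np.exp(-0.5 * ((wl - 450.0) / 20.0) ** 2)
    B = np.exp(-0.5 * ((wl - 560.0) / 30.0) ** 2)
    A /= A.sum()
    B /= B.sum()  # equal total intensity
    return A, B


def test_fraction_endpoints_and_midpoint():
    A, B = _refs()
    scene = _scene_from_spectra([A, B, 0.5 * A + 0.5 * B])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    pA, pB = phs.phasor_of_spectrum(A), phs.phasor_of_spectrum(B)
    frac = phs.linear_fraction(f, pA, pB)[0]
    assert frac[0] == pytest.approx(1.0, abs=1e-9)
    assert frac[1] == pytest.approx(0.0, abs=1e-9)
    assert frac[2] == pytest.approx(0.5, abs=1e-9)


def test_fraction_recovers_mixture_weight():
    A, B = _refs()
    ws = [0.0, 0.25, 0.5, 0.75, 1.0]
    scene = _scene_from_spectra([w * A + (1 - w) * B for w in ws])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    frac = phs.linear_fraction(f, phs.phasor_of_spectrum(A),
                               phs.phasor_of_spectrum(B))[0]
    assert np.max(np.abs(frac - ws)) < 1e-9


def test_degenerate_references_raise():
    A, _ = _refs()
    scene = _scene_from_spectra([A])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    p = phs.phasor_of_spectrum(A)
    with pytest.raises(ConfigurationError):
        phs.linear_fraction(f, p, p)


# --- fraction curves -------------------------------------------------------

def test_curve_center_of_mass_single_point():
    A, B = _refs()
    scene = _scene_from_spectra([0.5 * A + 0.5 * B] * 10)
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    frac = phs.linear_fraction(f, phs.phasor_of_spectrum(A),
                               phs.phasor_of_spectrum(B))
    curve = phs.fraction_curve(f, frac, bins=20)
    assert curve.center_of_mass == pytest.approx(0.5, abs=0.05)
    assert curve.values.max() == 1.0


def test_curve_symmetric_bimodal_com():
    A, B = _refs()
    scene = _scene_from_spectra([0.2 * A + 0.8 * B] * 5 + [0.8 * A + 0.2 * B] * 5)
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    frac = phs.linear_fraction(f, phs.phasor_of_spectrum(A),
                               phs.phasor_of_spectrum(B))
    curve = phs.fraction_curve(f, frac, bins=20)
    assert curve.center_of_mass == pytest.approx(0.5, abs=0.05)


def test_curve_com_matches_ground_truth_mixture():
    """With equal-intensity references the intensity-weighted COM equals
    the mean mixture weight to within a bin width."""
    A, B = _refs()
    rng = np.random.default_rng(3)
    ws = rng.uniform(0.1, 0.9, 200)
    scene = _scene_from_spectra([w * A + (1 - w) * B for w in ws])
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    frac = phs.linear_fraction(f, phs.phasor_of_spectrum(A),
                               phs.phasor_of_spectrum(B))
    curve = phs.fraction_curve(f, frac, bins=25)
    assert curve.center_of_mass == pytest.approx(ws.mean(), abs=1.0 / 25)


def test_degenerate_curve_flagged():
    A, B = _refs()
    scene = _scene_from_spectra([A] * 5)
    f = phs.spectral_phasor(scene, intensity_threshold=0.0)
    frac = phs.linear_fraction(f, phs.phasor_of_spectrum(A),
                               phs.phasor_of_spectrum(B))
    assert phs.fraction_curve(f, frac, bins=10).degenerate
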