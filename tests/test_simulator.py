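"""Simulator: background statistics, interferometric rendering, noise,
ground-truth generation."""

import numpy as np
import pytest

import iscatml as m
from iscatml.simulator import _draw_events


def test_zero_speckle_amplitude_gives_zero_field():
    cfg = m.SimConfig(shape=(32, 32), speckle_rms=0.0)
    field = m.make_speckle_background(cfg, m.OpticalModel(), seed=1)
    assert np.all(field == 0)


def test_speckle_deterministic_and_rms_calibrated():
    cfg = m.SimConfig(shape=(64, 64), speckle_rms=5e-3)
    a = m.make_speckle_background(cfg, m.OpticalModel(), seed=42)
    b = m.make_speckle_background(cfg, m.OpticalModel(), seed=42)
    assert np.array_equal(a, b)
    rms = np.sqrt(np.mean(a**2))
    assert abs(rms - 5e-3) / 5e-3 < 0.05
    assert abs(a.mean()) < 5e-4


def test_speckle_correlation_width_matches_psf():
    # autocorrelation of a PSF-filtered white field is Gaussian with
    # sigma * sqrt(2); its half-width therefore is HWHM * sqrt(2)
    cfg = m.SimConfig(shape=(128, 128), speckle_rms=1e-2)
    optics = m.OpticalModel()  # psf HWHM 2.5 px
    field = m.make_speckle_background(cfg, optics, seed=3)
    var = np.mean(field**2)
    corr = []
    for d in range(0, 10):
        c = (np.mean(field[:, :-d] * field[:, d:]) if d else var) / var
        corr.append(c)
    corr = np.array(corr)
    # brute-force half width by linear interpolation of the lag profile
    below = np.where(corr < 0.5)[0][0]
    frac = (0.5 - corr[below - 1]) / (corr[below] - corr[below - 1])
    half_width = below - 1 + frac
    expected = 2.5 * np.sqrt(2.0)
    assert abs(half_width - expected) / expected < 0.10


def test_render_flat_background_equals_reference_power():
    optics = m.OpticalModel()
    frame = m.render_frame(np.zeros((16, 16)), [], optics)
    assert np.allclose(frame, optics.reference_power)


def test_render_single_event_center_value():
    optics = m.OpticalModel()
    ev = m.LandingEvent(frame_index=0, row=8, col=8, mass_kda=66,
                        contrast=-0.01)
    frame = m.render_frame(np.zeros((17, 17)), [ev], optics)
    assert np.isclose(frame[8, 8], optics.reference_power * 0.99)


def test_render_superposition_of_separated_events():
    optics = m.OpticalModel()
    bg = m.make_speckle_background(m.SimConfig(shape=(48, 48)), optics, seed=5)
    e1 = m.LandingEvent(0, 10.0, 12.0, 66, -2e-3)
    e2 = m.LandingEvent(0, 35.0, 34.0, 66, -3e-3)
    both = m.render_frame(bg, [e1, e2], optics)
    single1 = m.render_frame(bg, [e1], optics)
    single2 = m.render_frame(bg, [e2], optics)
    bg_only = m.render_frame(bg, [], optics)
    assert np.allclose(both, single1 + single2 - bg_only)


def test_render_rejects_unphysical_negative_power():
    ev = m.LandingEvent(0, 8, 8, 1, -2.0)
    with pytest.raises(ValueError):
        m.render_frame(np.zeros((17, 17)), [ev], m.OpticalModel())


def test_noise_free_flag_only_quantizes():
    frame = np.full((32, 32), 1234.4)
    out = m.add_noise(frame, photon_budget=1234.4, bit_depth=16, seed=0,
                      noise=False)
    assert np.all(out == 1234)


def test_poisson_variance_matches_mean():
    n_photons = 1.0e4
    frame = np.full((320, 320), n_photons)
    out = m.add_noise(frame, n_photons, 16, seed=9).astype(float)
    # clipping at 2^16-1 = 65535 never triggers at this budget
    assert abs(out.var() - n_photons) / n_photons < 0.05
    same = m.add_noise(frame, n_photons, 16, seed=9).astype(float)
    assert np.array_equal(out, same)


def test_add_noise_rejects_nonpositive_budget():
    with pytest.raises(ValueError):
        m.add_noise(np.ones((4, 4)), 0.0, 16, seed=0)


def test_event_rate_zero_gives_background_only_stack():
    cfg = m.SimConfig(shape=(32, 32), n_frames=50, event_rate_hz=0.0)
    stack, tirf, truth = m.simulate_stack(cfg, seed=1)
    assert len(truth) == 0
    assert tirf is None
    assert stack.n_frames == 50


def test_ground_truth_contrast_is_linear_in_mass():
    cfg = m.SimConfig(shape=(48, 48), n_frames=60, masses_kda=[66.0] * 10,
                      contrast_slope=3e-5, event_frame_margin=5)
    _, _, truth = m.simulate_stack(cfg, seed=2)
    assert len(truth) == 10
    assert np.allclose(np.abs(truth["contrast"]), 1.98e-3)


def test_labeling_efficiency_bernoulli_thinning():
    # 1,000 events at efficiency 0.5: labeled count inside binomial 99% CI
    cfg = m.SimConfig(shape=(64, 64), n_frames=2000, tirf_enabled=True,
                      labeling_efficiency=0.5,
                      event_contrasts=[2e-3] * 1000,
                      min_event_separation_px=1.0)
    events = _draw_events(cfg, np.random.default_rng(11))
    n_labeled = sum(1 for e in events if e.channel == "both")
    half = 2.576 * np.sqrt(1000 * 0.25)
    assert abs(n_labeled - 500) <= half


def test_noise_free_stack_is_reproducible_and_step_shaped():
    cfg = m.SimConfig(shape=(32, 32), n_frames=40, noise=False,
                      drift_amplitude=0.0, event_contrasts=[5e-3],
                      event_frames=[20], bit_depth=16)
    s1, _, truth = m.simulate_stack(cfg, seed=4)
    s2, _, _ = m.simulate_stack(cfg, seed=4)
    assert np.array_equal(s1.data, s2.data)
    r, c = int(round(truth.row[0])), int(round(truth.col[0]))
    before = s1.data[:20, r, c].astype(float)
    after = s1.data[20:, r, c].astype(float)
    assert np.ptp(before) <= 1 and np.ptp(after) <= 1  # flat plateaus
    assert after.mean() < before.mean()  # negative-contrast step
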