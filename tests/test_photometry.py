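"""Photometry: DoG localization, V-trace extraction and fitting, population
analysis (GMM, MLE mode, bootstrap CI)."""

import numpy as np
import pytest

import iscatml as m
from conftest import make_tent
from iscatml.dra import differential_rolling_average
from iscatml.simulator import gaussian_psf, hwhm_to_sigma


def test_dog_localizes_subpixel_center():
    sigma = hwhm_to_sigma(2.5)
    frame = -4e-3 * gaussian_psf((48, 48), (20.3, 31.7), sigma)
    center = m.dog_localize(frame, psf_sigma=sigma)
    assert center is not None
    assert np.hypot(center[0] - 20.3, center[1] - 31.7) < 0.2
    # invariant to constant offsets
    center2 = m.dog_localize(frame + 0.05, psf_sigma=sigma)
    assert np.allclose(center, center2, atol=1e-6)


def test_dog_flags_flat_region_unlocalizable():
    rng = np.random.default_rng(0)
    flat = rng.normal(0, 1e-6, size=(32, 32))
    assert m.dog_localize(flat) is None


def test_v_trace_of_simulated_step_is_exact():
    cfg = m.SimConfig(shape=(32, 32), n_frames=400, noise=False,
                      drift_amplitude=0.0, speckle_rms=0.0, event_contrasts=[3e-3],
                      event_frames=[200], event_positions=[(16.0, 16.0)])
    stack, _, truth = m.simulate_stack(cfg, seed=1)
    ratio = differential_rolling_average(stack, m.DRAConfig(window=50))
    center = (truth.row[0], truth.col[0])
    peak = int(truth.frame[0]) - 50
    trace = m.extract_v_trace(ratio, center, peak, window=50)
    contrast, vertex, rms = m.fit_v_trace(trace)
    assert abs(contrast - 3e-3) / 3e-3 < 0.01
    assert vertex == pytest.approx(peak, abs=2)
    # background-only pixel gives a flat near-zero trace
    flat = m.extract_v_trace(ratio, (5.0, 5.0), peak, window=50)
    assert np.max(np.abs(flat.values)) < 3e-4
    # trace sign matches the configured negative contrast
    assert trace.values.min() == pytest.approx(-3e-3, rel=0.01)


def test_fit_exact_tent_to_machine_precision():
    trace = make_tent(depth=0.002, window=20)
    contrast, vertex, rms = m.fit_v_trace(trace)
    assert contrast == pytest.approx(0.002, rel=1e-9)
    assert vertex == 0
    assert rms < 1e-12


def test_fit_rejects_pure_line():
    t = np.arange(30)
    trace = m.ContrastTrace(frames=t, values=0.1 + 0.01 * t)
    with pytest.raises(ValueError, match="non-V"):
        m.fit_v_trace(trace)


def test_fit_recovers_noisy_tent_depth():
    depth = 0.002
    est = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        trace = make_tent(depth=depth, window=25)
        trace.values = trace.values + rng.normal(0, 0.2 * depth,
                                                 size=trace.values.size)
        c, _, _ = m.fit_v_trace(trace)
        est.append(c)
    assert abs(np.mean(est) - depth) / depth < 0.05


def test_contrast_estimate_is_scale_equivariant():
    trace = make_tent(depth=0.004, window=15, baseline=2e-4)
    c1, _, _ = m.fit_v_trace(trace)
    scaled = m.ContrastTrace(frames=trace.frames, values=5.0 * trace.values)
    c2, _, _ = m.fit_v_trace(scaled)
    assert c2 == pytest.approx(5.0 * c1, rel=1e-9)


def test_population_single_gaussian_recovery():
    rng = np.random.default_rng(7)
    x = rng.normal(2e-3, 2e-4, size=300)
    fit = m.fit_population(x, seed=0)
    assert fit.n_components == 1
    assert abs(fit.mode_contrast - 2e-3) < 3 * 2e-4 / np.sqrt(300)
    assert fit.ci_low < 2e-3 < fit.ci_high


def test_population_main_mode_is_lowest_component():
    rng = np.random.default_rng(8)
    mu = 2e-3
    x = np.concatenate([rng.normal(mu, 1.5e-4, 240),
                        rng.normal(2 * mu, 2e-4, 60)])
    fit = m.fit_population(x, seed=0)
    assert fit.n_components >= 2
    assert fit.mode_contrast == pytest.approx(mu, rel=0.08)


def test_bootstrap_ci_coverage(fixtures):
    mu, sd, n = 2e-3, 2e-4, 120
    covered = 0
    reps = 100
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        x = rng.normal(mu, sd, size=n)
        fit = m.fit_population(x, max_components=1, seed=rep, n_cycles=1001)
        covered += (fit.ci_low <= mu <= fit.ci_high)
    assert covered >= 90


def test_bootstrap_cycle_floor_enforced():
    x = np.random.default_rng(0).normal(2e-3, 2e-4, 50)
    with pytest.raises(ValueError, match="1000"):
        m.fit_population(x, n_cycles=1000)
    with pytest.raises(ValueError):
        m.fit_population(x[:5])


def test_degenerate_population_zero_width_ci():
    fit = m.fit_population(np.full(20, 1.5e-3), seed=0)
    assert fit.n_components == 1
    assert fit.mode_contrast == pytest.approx(1.5e-3)
    assert fit.ci_low == fit.ci_high == pytest.approx(1.5e-3)
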