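"""Differential rolling average: step response, gain invariance, masking,
background RMS estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import iscatml as m
from iscatml.dra import apply_field_mask, field_mask


def _dra_oracle_1px(trace, n):
    """Independent scalar DRA: explicit loop over the two running means."""
    out = []
    for t in range(n, len(trace) - n + 1):
        lead = sum(trace[t - n: t]) / n
        trail = sum(trace[t: t + n]) / n
        out.append(trail / lead - 1.0)
    return np.array(out)


def test_constant_stack_gives_zero_output():
    stack = np.full((30, 4, 4), 1000.0)
    out = m.differential_rolling_average(stack, m.DRAConfig(window=5))
    assert out.n_frames == 30 - 10 + 1
    assert np.allclose(out.data, 0.0)


def test_step_response_matches_scalar_oracle():
    n = 4
    c = 0.02
    trace = [100.0] * 12 + [100.0 * (1 + c)] * 12  # step at frame T = 12
    expected = _dra_oracle_1px(trace, n)
    stack = np.array(trace)[:, None, None] * np.ones((1, 1, 1))
    out = m.differential_rolling_average(stack, m.DRAConfig(window=n))
    got = out.data[:, 0, 0]
    assert np.allclose(got, expected, rtol=1e-10)
    # peak equals the step height c exactly, at output anchored to T
    assert np.isclose(got[12 - n], c)
    # V-shaped |ramp| over 2n-1 frames around the step
    peak = 12 - n
    assert np.all(np.diff(got[peak - n + 1: peak + 1]) > 0)
    assert np.all(np.diff(got[peak: peak + n]) < 0)


def test_gain_invariance():
    rng = np.random.default_rng(0)
    stack = 1000.0 + 50.0 * rng.random((40, 6, 6))
    cfg = m.DRAConfig(window=6)
    base = m.differential_rolling_average(stack, cfg).data
    scaled = m.differential_rolling_average(7.3 * stack, cfg).data
    assert np.allclose(base, scaled, atol=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(hnp.arrays(np.float64, (16, 3, 3),
                  elements=st.floats(100.0, 200.0)),
       st.floats(0.1, 50.0))
def test_gain_invariance_property(stack, gain):
    cfg = m.DRAConfig(window=4)
    base = m.differential_rolling_average(stack, cfg).data
    scaled = m.differential_rolling_average(gain * stack, cfg).data
    assert np.allclose(base, scaled, atol=1e-9)


def test_too_short_stack_rejected_with_minimum():
    with pytest.raises(ValueError, match="at least 20"):
        m.differential_rolling_average(np.ones((19, 2, 2)),
                                       m.DRAConfig(window=10))


def test_diff_mode_subtracts_instead_of_dividing():
    trace = [10.0] * 8 + [12.0] * 8
    stack = np.array(trace)[:, None, None]
    out = m.differential_rolling_average(stack, m.DRAConfig(window=4,
                                                            mode="diff"))
    assert np.isclose(out.data[4, 0, 0], 2.0)


def test_field_mask_geometry_brute_force():
    frame = np.ones((128, 128))
    masked = apply_field_mask(frame, 33.0)
    # brute-force distance test against the frame center
    cr = cc = (128 - 1) / 2.0
    for r in range(0, 128, 7):
        for c in range(0, 128, 7):
            inside = (r - cr) ** 2 + (c - cc) ** 2 <= 33.0**2
            assert np.isfinite(masked[r, c]) == inside
    # radius beyond the half-diagonal changes nothing
    assert np.all(np.isfinite(apply_field_mask(frame, 100.0)))
    # tiny radius keeps only the central pixels
    tiny = apply_field_mask(np.ones((5, 5)), 0.5)
    assert np.isfinite(tiny).sum() == 1


def test_background_rms_estimation():
    assert m.estimate_background_rms(np.zeros((3, 8, 8))) == 0.0
    rng = np.random.default_rng(1)
    field = rng.normal(0.0, 1e-3, size=(40, 32, 32))
    est = m.estimate_background_rms(field)
    assert abs(est - 1e-3) / 1e-3 < 0.03
    half = np.zeros((40, 32, 32), bool)
    half[:, :16] = True
    est_half = m.estimate_background_rms(field, half)
    assert abs(est_half - est) / est < 0.02
    with pytest.raises(ValueError):
        m.estimate_background_rms(field, np.ones_like(field, bool))


def test_snr_definition():
    assert m.snr_of_event(0.003, 0.001) == pytest.approx(3.0)
    assert m.snr_of_event(0.0, 0.001) == 0.0
    with pytest.raises(ValueError):
        m.snr_of_event(0.003, 0.0)


def test_background_rms_scales_as_inverse_sqrt_window():
    # static speckle cancels; shot noise drives the residual, so RMS ~ 1/sqrt(N)
    cfg = m.SimConfig(shape=(48, 48), n_frames=600, event_rate_hz=0,
                      drift_amplitude=0.0)
    stack, _, _ = m.simulate_stack(cfg, seed=8)
    rms = {}
    for n in (25, 250):
        ratio = m.differential_rolling_average(stack, m.DRAConfig(window=n))
        fm = field_mask(ratio.frame_shape, 20.0)
        rms[n] = m.estimate_background_rms(ratio, ~fm[None])
    assert abs(rms[25] / rms[250] - np.sqrt(10)) / np.sqrt(10) < 0.10


def test_noise_free_event_contrast_recovered_exactly():
    cfg = m.SimConfig(shape=(32, 32), n_frames=300, noise=False,
                      drift_amplitude=0.0, speckle_rms=0.0, event_contrasts=[4e-3],
                      event_frames=[150])
    stack, _, truth = m.simulate_stack(cfg, seed=12)
    ratio = m.differential_rolling_average(stack, m.DRAConfig(window=50))
    r, c = truth.row[0], truth.col[0]
    peak_idx = int(truth.frame[0]) - 50
    val = ratio.data[peak_idx, int(round(r)), int(round(c))]
    psf_peak = np.exp(-(((round(r) - r) ** 2 + (round(c) - c) ** 2))
                      / (2 * m.hwhm_to_sigma(2.5) ** 2))
    assert abs(abs(val) - 4e-3 * psf_peak) / (4e-3 * psf_peak) < 0.01


def test_background_only_dra_mean_vanishes(bg_ratio):
    rms = m.estimate_background_rms(bg_ratio)
    mean = np.nanmean(bg_ratio.data)
    assert abs(mean) < rms / np.sqrt(bg_ratio.window)
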