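"""Self-supervised denoiser: training behavior, residuals, probability maps,
probability-map classification."""

import numpy as np
import pytest

import iscatml as m
from iscatml.dra import differential_rolling_average
from iscatml.simulator import gaussian_psf, hwhm_to_sigma


def _small_cfg(**kw):
    kw.setdefault("stride", 3)
    kw.setdefault("epochs", 12)
    kw.setdefault("batches_per_epoch", 30)
    kw.setdefault("seed", 0)
    return m.DenoiserConfig(**kw)


def test_constant_stack_learns_identity():
    rng = np.random.default_rng(0)
    pattern = rng.normal(0, 1e-3, size=(32, 32))
    stack = np.repeat(pattern[None], 80, axis=0)
    model = m.train_denoiser(stack, _small_cfg(epochs=25))
    res = m.residual_map(model, stack, 40)
    input_rms = np.sqrt(np.mean(pattern**2))
    assert np.sqrt(np.mean(res**2)) < 0.10 * input_rms


def test_white_noise_is_unpredictable():
    rng = np.random.default_rng(1)
    stack = rng.normal(0, 1e-3, size=(90, 32, 32))
    model = m.train_denoiser(stack, _small_cfg())
    res = np.stack([m.residual_map(model, stack, t) for t in (20, 45, 70)])
    # nothing is predictable: residual RMS stays at the noise RMS
    ratio = np.sqrt(np.mean(res**2)) / 1e-3
    assert 0.85 < ratio < 1.30


def test_training_is_seed_reproducible():
    rng = np.random.default_rng(2)
    stack = rng.normal(0, 1e-3, size=(70, 24, 24))
    l1 = m.train_denoiser(stack, _small_cfg(seed=5)).loss_history[-1]
    l2 = m.train_denoiser(stack, _small_cfg(seed=5)).loss_history[-1]
    assert l1 == pytest.approx(l2, abs=1e-12)


def test_training_rejects_short_stack():
    with pytest.raises(ValueError, match="triplet"):
        m.train_denoiser(np.zeros((20, 8, 8)), _small_cfg(stride=5))


def test_target_frame_never_an_input():
    with pytest.raises(ValueError):
        m.DenoiserConfig(stride=2, offsets=[0, 2])


def test_loss_decreases_on_drifting_background(fixtures, bg_ratio):
    # structured (drift) background is learnable: smoothed loss decreases
    cfg = m.DenoiserConfig(stride=2 * bg_ratio.window, epochs=15, seed=1)
    model = m.train_denoiser(bg_ratio, cfg)
    loss = np.array(model.loss_history)
    k = 5
    smoothed = np.convolve(loss, np.ones(k) / k, mode="valid")
    assert smoothed[-1] < smoothed[0]
    # denoising does not amplify the background
    res = np.stack([m.residual_map(model, bg_ratio, t)
                    for t in range(250, bg_ratio.n_frames - 250, 100)])
    assert (np.sqrt(np.nanmean(res**2))
            < 1.05 * np.sqrt(np.nanmean(bg_ratio.data**2)))


def test_step_event_survives_in_residual():
    # noise-free simulation: residual at the event center at the transient
    # peak recovers the DRA contrast within 30%
    cfg = m.SimConfig(shape=(32, 32), n_frames=500, noise=False,
                      drift_amplitude=0.0, speckle_rms=0.0, event_contrasts=[5e-3],
                      event_frames=[250])
    stack, _, truth = m.simulate_stack(cfg, seed=3)
    ratio = differential_rolling_average(stack, m.DRAConfig(window=50))
    model = m.train_denoiser(ratio, m.DenoiserConfig(stride=100, epochs=12,
                                                     seed=2))
    peak = int(truth.frame[0]) - 50
    res = m.residual_map(model, ratio, peak)
    r, c = int(round(truth.row[0])), int(round(truth.col[0]))
    assert abs(abs(res[r, c]) - 5e-3) / 5e-3 < 0.30


def test_probability_map_conventions():
    flat = m.probability_map(np.full((8, 8), 0.7))
    assert np.allclose(flat.values, 0.5)  # all ties -> midrank
    rng = np.random.default_rng(4)
    res = rng.normal(size=(16, 16))
    pm = m.probability_map(res)
    order_in = np.argsort(np.abs(res).ravel())
    order_out = np.argsort(pm.values.ravel())
    assert np.array_equal(order_in, order_out)  # strictly monotone
    scaled = m.probability_map(3.7 * res)
    assert np.allclose(pm.values, scaled.values)  # scale invariant


def test_top_rank_hits_event_center():
    sigma = hwhm_to_sigma(2.5)
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        res = rng.normal(0, 1e-3, size=(48, 48))
        res += 5e-3 * gaussian_psf((48, 48), (20, 30), sigma)
        sm = m.smooth_residual(res, sigma)
        pm = m.probability_map(sm)
        r, c = np.unravel_index(np.argmax(pm.values), pm.values.shape)
        hits += (abs(r - 20) <= 1 and abs(c - 30) <= 1)
    assert hits >= 18


def test_classify_probability_maps_blob_and_determinism():
    base = np.full((32, 32), 0.5)
    with pytest.warns(UserWarning, match="degenerate"):
        empty = m.classify_probability_maps([base], seed=0)
    assert not empty.mask.any()

    rng = np.random.default_rng(6)
    pm = m.probability_map(rng.normal(size=(32, 32))).values
    blob = pm.copy()
    blob[10:13, 20:23] = 1.0  # saturated PSF-sized blob
    mask = m.classify_probability_maps([blob], contamination=0.02, seed=1)
    assert mask.mask[10:13, 20:23].all()
    again = m.classify_probability_maps([blob], contamination=0.02, seed=1)
    assert np.array_equal(mask.mask, again.mask)
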