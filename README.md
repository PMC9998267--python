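# iscatml

Machine-learning detection of single-protein landing events in
interferometric scattering (iSCAT) video, with single-event contrast
photometry and linear mass calibration — plus a physics-grounded synthetic
video simulator that makes every stage testable without experimental data.

## The problem

iSCAT microscopy detects label-free single proteins through the interference
between the light they scatter and a reference reflection.  The detected
power per pixel is

    P_d ∝ |E_r|² + |E_s|² + 2|E_r||E_s| cos φ,       E_r = r·E_i,  E_s = s·E_i,

and because |E_s|² is negligible for a single protein, the interferometric
contrast

    C = (P_d − P_r)/P_r ≈ 2 (s/r) cos φ

is linear in the particle's polarizability, hence — at roughly constant
protein density and refractive index — **linear in molecular mass**.  That
makes iSCAT a mass photometer, but only if single-protein landing events can
be pulled out of a speckle-like coherent background whose slow residual
dynamics, not shot noise, limit sensitivity in practice.

This package implements the detection pipeline that pushes that limit:

1. **DRA** — differential rolling average: each frame block is divided by
   the preceding block, pixel-wise, cancelling static background and turning
   a landing step into a V-shaped (triangular) contrast transient.
2. **Anomaly detection**, two parallel paths over the ratiometric video:
   - *user-defined features*: per-pixel temporal statistics (mean, std,
     slope, extrema) and spatial statistics (PSF-template correlation,
     local variance) classified by an **isolation forest**;
   - *self-supervised denoiser*: a small convolutional regressor trained on
     the video itself to predict frame *t* from frames *t−k* and *t+k*;
     the prediction residual suppresses everything predictable (speckle,
     slow drift), residual magnitudes are rank-normalized into per-pixel
     **probability maps**, and an isolation forest flags event pixels.
3. **Morphological filtering** (events are PSFs: isolated anomalous pixels
   are discarded) and **consolidation**: hot pixels are accumulated per
   detection window, convolved with the instrument PSF (HWHM 2.5 px), and
   distinct events are extracted greedily under a binary-mask non-overlap
   rule (radius 5 px), followed by a matched-filter verification of each
   candidate's landing transient.
4. **Photometry**: difference-of-Gaussians sub-pixel localization, V-trace
   extraction from the DRA video, two-line fit for the event contrast, and
   population analysis (Gaussian mixture, maximum-likelihood main mode,
   bootstrap confidence intervals with >1,000 cycles).
5. **Calibration**: ordinary least-squares contrast↔mass ladder with
   per-point accuracy (kDa) and precision (% of mass), and iSCAT/TIRF
   coincidence analysis against a fluorescence channel.

The simulator generates the matching synthetic data: PSF-correlated static
speckle, smooth multiplicative drift, Poisson shot noise at a configurable
photon budget, camera quantization, step-in-time landing events with
contrast linear in mass, and an optional TIRF channel with imperfect
labeling.

## Worked example

```python
import iscatml as m

cfg = m.PipelineConfig(
    seed=11,
    sim=m.SimConfig(shape=(64, 64), n_frames=3000,
                    event_contrasts=[6e-3] * 6, event_rate_hz=0.0,
                    event_frames=[800, 1100, 1400, 1700, 2000, 2300]),
    dra=m.DRAConfig(window=200),
    detector=m.DetectorConfig(path="dnn"),
)
report = m.run_pipeline(cfg)
p = report["paths"]["dnn"]
print(f"background RMS {p['background_rms']:.2e}, "
      f"{p['n_events']} events, recall {p['metrics']['recall']:.2f}")
for e in p["events"][:3]:
    c = "None" if e["contrast"] is None else f"{e['contrast']:.2e}"
    print(f"  event at ({e['row']:.1f}, {e['col']:.1f}), contrast {c}")
```

prints (seed 11):

```
background RMS 1.35e-03, 6 events, recall 1.00
  event at (45.0, 48.3), contrast None
  event at (54.4, 31.7), contrast 7.02e-03
  event at (54.1, 18.0), contrast None
```

Six simulated landings of contrast 6×10⁻³ on a drifting speckle background:
all six are recovered within 3 px of the ground truth with no false
positives; the fitted V-trace contrasts scatter around the simulated value
(events whose trace fails the two-line fit keep no contrast — they still
count as detections).  Feeding main-mode contrasts of several such runs at
different masses into `fit_mass_ladder` returns the slope in contrast/kDa
that converts any future contrast to mass.

A CLI mirrors the library: `iscatml simulate | dra | detect-features |
detect-dnn | photometry | calibrate | coincide | run` (see `iscatml --help`).

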