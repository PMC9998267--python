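"""Synthetic iSCAT / TIRF video generation with ground-truth landing events.

The simulator produces camera-frame stacks that reproduce the statistical
structure of interferometric scattering (iSCAT) video of a coverglass in
buffer: a static speckle-like background whose spatial correlation length is
set by the instrument point spread function (PSF), a slow multiplicative
drift of that background, shot noise at a configurable photon budget, camera
quantization, and sparse single-protein landing events.  Each landing event
is a diffraction-limited Gaussian PSF whose interferometric contrast

    C = (P_d - P_r) / P_r ~ 2 (s / r) cos(phi)

is linear in molecular mass (the polarizability of a protein scales with its
volume, and protein density is approximately constant).  A landing event is a
step in time: contrast 0 before the landing frame, C afterwards.

An optional TIRF channel renders the fluorescently labeled subset of the same
events (Bernoulli thinning at the labeling efficiency) as bright spots on an
incoherent background, for coincidence validation of the label-free channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

__all__ = [
    "OpticalModel",
    "LandingEvent",
    "SimConfig",
    "FrameStack",
    "hwhm_to_sigma",
    "gaussian_psf",
    "make_speckle_background",
    "render_frame",
    "add_noise",
    "simulate_stack",
]

# HWHM of a Gaussian = sigma * sqrt(2 ln 2)
_HWHM_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))

#: Default instrument PSF half-width at half maximum, in pixels.  The
#: experimental PSF of the target instrument class is well fitted by an
#: isotropic Gaussian of HWHM 2.5 px.
DEFAULT_PSF_HWHM = 2.5


def hwhm_to_sigma(hwhm: float) -> float:
    """Convert a Gaussian half-width at half maximum to a standard deviation."""
    return float(hwhm) / _HWHM_FACTOR


class OpticalModel(BaseModel):
    """Interferometric detection parameters.

    The detected power per pixel is modeled as

        P_d = P_r * (1 + C_bg + sum_events C_i * G_i)

    with reference power ``P_r = r**2 * P_i``.  The pure scattered-intensity
    term |E_s|^2 is negligible for single proteins and omitted.

    Parameters
    ----------
    reference_amplitude:
        Field reflectivity ``r`` of the coverglass/buffer interface, in (0, 1].
    incident_power:
        Incident photon budget ``P_i`` (photons / pixel / frame).
    psf_sigma:
        Gaussian sigma of the instrument PSF in pixels.
    phase:
        Interferometric phase ``phi`` (radians), fixed per stack.  Only its
        sign convention matters here: event contrasts carry their own sign.
    wavelength_nm:
        Illumination wavelength; metadata only.
    """

    reference_amplitude: float = Field(0.1, gt=0.0, le=1.0)
    incident_power: float = Field(2.0e6, gt=0.0)
    psf_sigma: float = Field(hwhm_to_sigma(DEFAULT_PSF_HWHM), gt=0.0)
    phase: float = np.pi
    wavelength_nm: float = 445.0

    @property
    def reference_power(self) -> float:
        """Reference power P_r = r^2 * P_i (photons / pixel / frame)."""
        return self.reference_amplitude**2 * self.incident_power


@dataclass(frozen=True)
class LandingEvent:
    """Ground-truth single-protein landing event.

    ``contrast`` is the signed peak interferometric contrast of the event
    PSF; it equals ``slope * mass`` for the stack-level calibration slope.
    Coordinates are 0-based (row, col) with pixel centers at integers.
    """

    frame_index: int
    row: float
    col: float
    mass_kda: float
    contrast: float
    channel: Literal["iscat", "tirf", "both"] = "iscat"


class SimConfig(BaseModel):
    """Stack-level simulation parameters.

    Defaults reflect the acquisition regime of small-protein mass photometry:
    kHz frame rates, landing rates well below one event per second so that
    events are sparse, and a speckle background at the few-1e-3 contrast
    level.  ``contrast_slope`` (contrast per kDa) fixes the linear
    contrast-mass relation used for ground truth; its default 3e-5 puts a
    66 kDa protein at ~2e-3 contrast.
    """

    shape: tuple[int, int] = (64, 64)
    n_frames: int = Field(5000, ge=2)
    frame_rate_hz: float = Field(5000.0, gt=0.0)
    #: static coherent background from substrate imperfections; 1.5e-2
    #: contrast RMS with the default drift puts the residual DRA background
    #: in the structured-background-limited regime, where slow drift of the
    #: speckle, not shot noise, dominates the residual fluctuations
    speckle_rms: float = Field(1.5e-2, ge=0.0)
    drift_amplitude: float = Field(0.3, ge=0.0)
    drift_tau_frames: float = Field(1000.0, gt=0.0)
    bit_depth: int = Field(16, ge=8, le=16)
    noise: bool = True
    event_rate_hz: float = Field(0.5, ge=0.0)
    masses_kda: list[float] | None = None
    contrast_slope: float = 3.0e-5
    contrast_sign: Literal[-1, 1] = -1
    #: explicit per-event |contrast| overrides (bypasses mass * slope)
    event_contrasts: list[float] | None = None
    #: explicit event frame indices; drawn uniformly if None
    event_frames: list[int] | None = None
    #: explicit event centers (row, col); drawn uniformly in the field if None
    event_positions: list[tuple[float, float]] | None = None
    #: frame range events may land in (margins keep them analyzable)
    event_frame_margin: int = 0
    #: minimum center-to-center spacing for temporally overlapping events (px)
    min_event_separation_px: float = 12.0
    tirf_enabled: bool = False
    labeling_efficiency: float = Field(0.7, ge=0.0, le=1.0)
    tirf_spot_amplitude: float = 200.0
    tirf_background: float = 100.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.event_contrasts is not None and self.masses_kda is not None:
            if len(self.event_contrasts) != len(self.masses_kda):
                raise ValueError("event_contrasts and masses_kda length mismatch")
        return self


@dataclass
class FrameStack:
    """A 3D stack of camera frames plus acquisition metadata.

    ``data`` has shape (n_frames, n_rows, n_cols).  Raw camera stacks are in
    photon-count (or digitized count) units; ratiometric stacks produced by
    the DRA are dimensionless contrast.
    """

    data: np.ndarray
    frame_rate_hz: float = 1.0
    exposure_s: float | None = None
    units: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be 3D (frames, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def gaussian_psf(shape: tuple[int, int], center: tuple[float, float],
                 sigma: float) -> np.ndarray:
    """Unit-peak isotropic Gaussian PSF at a sub-pixel center.

    The peak amplitude (value at the exact center) is 1; sampled on the
    pixel grid the maximum pixel value can be slightly below 1 for
    off-integer centers.
    """
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.exp(-r2 / (2.0 * sigma**2))


def make_speckle_background(config: SimConfig, optics: OpticalModel,
                            seed: int | np.random.Generator) -> np.ndarray:
    """Static speckle-like background field, in contrast units.

    Coherent scattering from substrate imperfections produces a background
    whose spatial correlations are set by the same instrument response that
    shapes a single-protein PSF.  This is modeled with minimal assumptions as
    white Gaussian noise low-pass filtered by the Gaussian PSF and rescaled
    so its RMS equals ``config.speckle_rms``.  Zero mean by construction;
    deterministic for a fixed seed.
    """
    if config.speckle_rms < 0:
        raise ValueError("speckle RMS must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(config.shape)
    if config.speckle_rms == 0:
        return np.zeros(config.shape)
    filtered = ndimage.gaussian_filter(white, optics.psf_sigma, mode="wrap")
    filtered -= filtered.mean()
    rms = np.sqrt(np.mean(filtered**2))
    return filtered * (config.speckle_rms / rms)


def render_frame(background: np.ndarray, events_active: Sequence[LandingEvent],
                 optics: OpticalModel, t: int = 0) -> np.ndarray:
    """Noise-free detected power per pixel for one frame.

    ``P_d = P_r * (1 + C_bg + sum_i C_i * G(center_i, psf_sigma))`` where
    ``C_bg`` is the background contrast field and each active event
    contributes its signed contrast scaled by a unit-peak Gaussian PSF.
    Raises on unphysical parameter combinations that would make the total
    power negative anywhere.
    """
    contrast = np.array(background, dtype=float, copy=True)
    for ev in events_active:
        if not (0 <= ev.row < background.shape[0] and 0 <= ev.col < background.shape[1]):
            raise ValueError(f"event center {(ev.row, ev.col)} outside frame")
        contrast += ev.contrast * gaussian_psf(background.shape, (ev.row, ev.col),
                                               optics.psf_sigma)
    frame = optics.reference_power * (1.0 + contrast)
    if np.any(frame < 0):
        raise ValueError("negative detected power: unphysical parameters")
    return frame


def add_noise(frame: np.ndarray, photon_budget: float, bit_depth: int,
              seed: int | np.random.Generator, *, noise: bool = True) -> np.ndarray:
    """Shot noise and camera quantization.

    ``frame`` must already be in photon units (its values are the Poisson
    means; ``photon_budget`` is the nominal reference level used only for
    validation).  With ``noise=False`` only quantization is applied, the
    infinite-photon limit.
    """
    if photon_budget <= 0:
        raise ValueError("photon budget must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = rng.poisson(frame).astype(np.float64) if noise else np.asarray(frame, float)
    max_count = 2**bit_depth - 1
    return np.clip(np.rint(out), 0, max_count).astype(np.uint16 if bit_depth <= 16 else np.uint32)


def _smooth_drift(n: int, tau: float, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth stationary drift path (mean 0, std sigma, correlation time tau).

    Gaussian-filtered white noise: a differentiable process whose local
    behavior is nearly linear over spans much shorter than ``tau``.  This is
    the structure of real mechanical/thermal background dynamics, and it is
    what makes the residual background partly predictable from temporally
    neighboring frames — the property the self-supervised denoiser exploits.
    """
    white = rng.standard_normal(n + int(6 * tau))
    smooth = ndimage.gaussian_filter1d(white, tau, mode="nearest")
    smooth = smooth[int(3 * tau): int(3 * tau) + n]
    sd = smooth.std()
    if sd == 0:
        return np.zeros(n)
    return sigma * (smooth - smooth.mean()) / sd


def _draw_events(config: SimConfig, rng: np.random.Generator) -> list[LandingEvent]:
    """Sample ground-truth landing events under the configured conditions.

    Temporally proximate events (within 4x the drift-free analyzability
    horizon, approximated as 800 frames) are kept at least
    ``min_event_separation_px`` apart so that their detection masks cannot
    merge; events well separated in time may recur anywhere.
    """
    duration_s = config.n_frames / config.frame_rate_hz
    if config.event_contrasts is not None:
        n_events = len(config.event_contrasts)
    elif config.masses_kda is not None:
        n_events = len(config.masses_kda)
    else:
        n_events = rng.poisson(config.event_rate_hz * duration_s)
    if n_events == 0:
        return []

    margin = config.event_frame_margin
    lo, hi = margin, config.n_frames - 1 - margin
    if hi < lo:
        raise ValueError("event frame margin leaves no admissible frames")
    if config.event_frames is not None:
        frames = [int(f) for f in config.event_frames]
        if len(frames) != n_events:
            raise ValueError("event_frames length mismatch")
    else:
        frames = sorted(int(f) for f in rng.integers(lo, hi + 1, size=n_events))

    nrow, ncol = config.shape
    center = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    rmax = min(nrow, ncol) / 2.0 - 4.0
    if config.event_positions is not None:
        if len(config.event_positions) != n_events:
            raise ValueError("event_positions length mismatch")
        positions = [tuple(map(float, p)) for p in config.event_positions]
        return _assemble_events(config, frames, positions, rng)
    positions = []
    for i in range(n_events):
        for _attempt in range(500):
            r = rmax * np.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            pos = (center[0] + r * np.sin(theta), center[1] + r * np.cos(theta))
            ok = True
            for j, p in enumerate(positions):
                if abs(frames[i] - frames[j]) <= 800:
                    if np.hypot(pos[0] - p[0], pos[1] - p[1]) < config.min_event_separation_px:
                        ok = False
                        break
            if ok:
                break
        positions.append(pos)
    return _assemble_events(config, frames, positions, rng)


def _assemble_events(config: SimConfig, frames, positions,
                     rng: np.random.Generator) -> list[LandingEvent]:
    events = []
    for i in range(len(frames)):
        if config.event_contrasts is not None:
            c = config.contrast_sign * abs(config.event_contrasts[i])
            mass = abs(c) / config.contrast_slope
        else:
            mass = (config.masses_kda[i] if config.masses_kda is not None
                    else 66.0)
            c = config.contrast_sign * config.contrast_slope * mass
        labeled = (config.tirf_enabled
                   and rng.uniform() < config.labeling_efficiency)
        events.append(LandingEvent(
            frame_index=frames[i], row=positions[i][0], col=positions[i][1],
            mass_kda=mass, contrast=c,
            channel="both" if labeled else "iscat"))
    return events


def _events_to_table(events: Sequence[LandingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"frame": e.frame_index, "row": e.row, "col": e.col,
          "mass_kda": e.mass_kda, "contrast": e.contrast, "channel": e.channel}
         for e in events],
        columns=["frame", "row", "col", "mass_kda", "contrast", "channel"])


def simulate_stack(config: SimConfig, optics: OpticalModel | None = None,
                   seed: int | None = None,
                   ) -> tuple[FrameStack, FrameStack | None, pd.DataFrame]:
    """Simulate a full acquisition: iSCAT stack, optional TIRF stack, truth table.

    Every landing event is a temporal step: its PSF contrast is 0 before
    ``frame_index`` and its full value from that frame on.  The static
    speckle background is modulated by a slow smooth drift of relative
    amplitude ``drift_amplitude`` and correlation time ``drift_tau_frames``,
    standing in for the slow electronic / mechanical / fluidic background
    dynamics that DRA cannot fully cancel but that are predictable from
    neighboring frames.

    Returns ``(iscat_stack, tirf_stack_or_None, ground_truth)`` where the
    truth table has columns frame, row, col, mass_kda, contrast, channel.
    """
    optics = optics or OpticalModel()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    rng_speckle, rng_events, rng_drift, rng_shot, rng_tirf = (
        np.random.default_rng(s) for s in root.spawn(5))

    speckle = make_speckle_background(config, optics, rng_speckle)
    events = _draw_events(config, rng_events)
    drift = (_smooth_drift(config.n_frames, config.drift_tau_frames,
                           config.drift_amplitude, rng_drift)
             if config.drift_amplitude > 0 else np.zeros(config.n_frames))

    # pre-render each event's PSF once; a step in time turns it on
    psfs = [ev.contrast * gaussian_psf(config.shape, (ev.row, ev.col),
                                        optics.psf_sigma) for ev in events]
    p_r = optics.reference_power
    max_count = 2**config.bit_depth - 1
    out = np.empty((config.n_frames, *config.shape), dtype=np.uint16)
    event_field = np.zeros(config.shape)
    next_event = 0
    order = np.argsort([e.frame_index for e in events])
    for t in range(config.n_frames):
        while next_event < len(events) and events[order[next_event]].frame_index <= t:
            event_field = event_field + psfs[order[next_event]]
            next_event += 1
        contrast = speckle * (1.0 + drift[t]) + event_field
        frame = p_r * (1.0 + contrast)
        if config.noise:
            frame = rng_shot.poisson(frame)
        out[t] = np.clip(np.rint(frame), 0, max_count)
    iscat = FrameStack(out, frame_rate_hz=config.frame_rate_hz,
                       units="counts", meta={"reference_power": p_r})

    tirf = None
    if config.tirf_enabled:
        tirf_data = np.empty_like(out)
        spot_sigma = optics.psf_sigma * 631.0 / optics.wavelength_nm
        labeled = [(e, gaussian_psf(config.shape, (e.row, e.col), spot_sigma))
                   for e in events if e.channel == "both"]
        base = np.full(config.shape, config.tirf_background)
        for t in range(config.n_frames):
            mean = base.copy()
            for e, psf in labeled:
                if e.frame_index <= t:
                    mean = mean + config.tirf_spot_amplitude * psf
            if config.noise:
                mean = rng_tirf.poisson(mean)
            tirf_data[t] = np.clip(np.rint(mean), 0, max_count)
        tirf = FrameStack(tirf_data, frame_rate_hz=config.frame_rate_hz,
                          units="counts")

    return iscat, tirf, _events_to_table(events)
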