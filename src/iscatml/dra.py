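"""Differential rolling average (DRA): ratiometric background suppression.

Raw iSCAT frames are dominated by the static reference reflection and the
speckle-like coherent background.  The DRA compares each point in time with
its neighbors: the mean of the N frames starting at t is divided by the mean
of the N frames preceding t, minus one, pixel-wise.  Static structure cancels
exactly and the output is directly in contrast units, so a landing step of
relative height C becomes a triangular (V-shaped) transient of peak |C|
spanning 2N-1 output frames.

Output frame indexing is anchored to the first frame of the trailing
(later) half-window: output index i of a stack of length T corresponds to
raw frame t = i + N, for i in [0, T - 2N].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field

from .simulator import FrameStack

__all__ = [
    "DRAConfig",
    "RatiometricStack",
    "differential_rolling_average",
    "apply_field_mask",
    "field_mask",
    "estimate_background_rms",
    "snr_of_event",
]


class DRAConfig(BaseModel):
    """DRA parameters.

    ``window`` is the number of frames N in each half-average (the regimes of
    interest use several hundred to several thousand).  ``stride`` subsamples
    the output stack for downstream analysis.  ``mask_radius`` is the radius
    R in pixels of the circular field mask that removes border/corner
    artifacts from all statistics (R = 33 px for the instrument class this
    models).  ``mode`` selects ratiometric ('ratio', default: trailing mean /
    leading mean - 1) or difference ('diff': trailing mean - leading mean)
    comparison of the two half-windows.
    """

    window: int = Field(200, ge=1)
    stride: int = Field(1, ge=1)
    mask_radius: float = Field(33.0, gt=0.0)
    mode: str = "ratio"


@dataclass
class RatiometricStack:
    """Pixel-wise contrast stack produced by the DRA.

    ``data[i]`` corresponds to raw frame ``i + window`` (first frame of the
    trailing half-average).
    """

    data: np.ndarray
    window: int
    source: str = ""
    mode: str = "ratio"
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def raw_index(self, i: int) -> int:
        """Raw-stack frame index corresponding to output index ``i``."""
        return i + self.window


def differential_rolling_average(stack: FrameStack | np.ndarray,
                                 config: DRAConfig) -> RatiometricStack:
    """Compute the DRA contrast stack.

    For each admissible t, ``out[t - N] = mean(raw[t : t+N]) /
    mean(raw[t-N : t]) - 1`` (ratio mode) evaluated pixel-wise in floating
    point; output length is ``T - 2N + 1``.  The ratio makes the output
    invariant under any global gain applied to the raw counts.
    """
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    n = config.window
    t_total = data.shape[0]
    if t_total < 2 * n:
        raise ValueError(
            f"stack of {t_total} frames too short for window {n}; "
            f"need at least {2 * n}")
    # running block means via cumulative sum along time
    csum = np.cumsum(data.astype(np.float64), axis=0)
    zero = np.zeros((1, *data.shape[1:]))
    csum = np.concatenate([zero, csum], axis=0)  # csum[t] = sum of frames < t
    block = (csum[n:] - csum[:-n]) / n           # block[t] = mean(raw[t:t+n])
    leading = block[: t_total - 2 * n + 1]       # mean(raw[t-n : t]), t = n...
    trailing = block[n:]                         # mean(raw[t : t+n])
    if config.mode == "ratio":
        out = trailing / leading - 1.0
    elif config.mode == "diff":
        out = trailing - leading
    else:
        raise ValueError(f"unknown DRA mode {config.mode!r}")
    return RatiometricStack(out.astype(np.float32), window=n, mode=config.mode)


def field_mask(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Boolean mask of pixels whose center lies within ``radius`` of the
    frame center (True = inside the analyzed field)."""
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def apply_field_mask(frame: np.ndarray, radius: float) -> np.ndarray:
    """Set pixels outside the circular field mask to NaN.

    NaN is the sentinel excluded from all downstream statistics.  Border and
    corner pixels carry DRA artifacts and are never analyzed.
    """
    frame = np.asarray(frame, dtype=float)
    out = frame.copy()
    out[~field_mask(frame.shape, radius)] = np.nan
    return out


def estimate_background_rms(ratio_stack: RatiometricStack | np.ndarray,
                            exclusion_masks: np.ndarray | None = None) -> float:
    """RMS of residual background contrast over event-free, unmasked pixels.

    ``exclusion_masks`` (same shape as the stack, or one frame broadcast)
    marks pixels to exclude (True = exclude), e.g. known event regions or
    the field-mask complement.  NaNs are always excluded.  This RMS is the
    noise level against which event SNR is defined.
    """
    data = ratio_stack.data if isinstance(ratio_stack, RatiometricStack) else np.asarray(ratio_stack)
    data = np.asarray(data, dtype=float)
    keep = np.isfinite(data)
    if exclusion_masks is not None:
        excl = np.broadcast_to(np.asarray(exclusion_masks, bool), data.shape)
        keep &= ~excl
    vals = data[keep]
    if vals.size == 0:
        raise ValueError("no unmasked pixels to estimate background RMS from")
    return float(np.sqrt(np.mean(vals**2)))


def snr_of_event(contrast: float, sigma: float) -> float:
    """Event signal-to-noise ratio |C| / sigma.

    ``sigma`` is the RMS of the residual background fluctuations in the DRA
    image (see :func:`estimate_background_rms`).
    """
    if sigma <= 0:
        raise ValueError("background RMS must be positive")
    return abs(contrast) / sigma
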