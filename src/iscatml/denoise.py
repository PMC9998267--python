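"""Self-supervised denoiser path: predict, subtract, rank, classify.

The idea: everything in a ratiometric iSCAT video that is *predictable from
neighboring frames* — residual speckle, slow drift — is background.  A small
convolutional regressor is trained, on the video itself and with no labels,
to predict frame t from frames t-k and t+k.  Subtracting the prediction from
frame t leaves a residual in which static and slowly varying structure is
suppressed while transient structure (a protein landing between t-k and t)
survives.  Residual magnitudes are rank-normalized into per-pixel anomaly
probability maps, and an isolation forest over the maps of neighboring
analysis frames flags event pixels.

The regressor is deliberately tiny (a few 3x3 conv layers, < 1e3 weights):
the prediction task is close to linear, desk-scale training must be cheap,
and low capacity is itself a safeguard against memorizing the rare events.
It is implemented directly on numpy (im2col convolutions, ReLU, Adam,
mean-squared loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, stats

from .dra import RatiometricStack
from .features import AnomalyMask

__all__ = [
    "DenoiserConfig",
    "DenoiserModel",
    "ProbabilityMap",
    "train_denoiser",
    "residual_map",
    "smooth_residual",
    "probability_map",
    "classify_probability_maps",
]


class DenoiserConfig(BaseModel):
    """Denoiser training configuration.

    ``stride`` is k, in ratiometric-stack frames: the input frames are t-k
    and t+k.  k should exceed the temporal footprint of one landing transient
    (2x the DRA half-window) so that for an event peaking at t both inputs
    are event-free.  Capacity, epochs and learning rate are small by design;
    all are exposed.
    """

    stride: int = Field(..., ge=1)
    offsets: list[int] | None = None  # defaults to [-k, +k]
    channels: int = Field(8, ge=1)
    depth: int = Field(3, ge=2)
    epochs: int = Field(15, ge=1)
    learning_rate: float = Field(5e-3, gt=0.0)
    batch_size: int = Field(8, ge=1)
    batches_per_epoch: int = Field(40, ge=1)
    patch_size: int = Field(32, ge=8)
    seed: int = 0

    @model_validator(mode="after")
    def _check_offsets(self) -> "DenoiserConfig":
        if self.offsets is None:
            object.__setattr__(self, "offsets", [-self.stride, self.stride])
        if 0 in self.offsets:
            raise ValueError("offset 0 not allowed: target frame must never "
                             "be an input")
        return self


@dataclass
class ProbabilityMap:
    """Per-pixel anomaly probability in [0, 1] for one analysis frame."""

    values: np.ndarray
    frame_index: int
    normalization: str = "rank"
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# minimal conv-net machinery (3x3 kernels, zero padding, 'same' output)

_OFFSETS3 = [(di, dj) for di in range(3) for dj in range(3)]


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (B, Cin, H, W); w: (Cout, Cin, 9); returns (y, cols)."""
    bsz, cin, h, wd = x.shape
    xp = np.zeros((bsz, cin, h + 2, wd + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    cols = np.empty((bsz, cin, 9, h, wd), dtype=x.dtype)
    for idx, (di, dj) in enumerate(_OFFSETS3):
        cols[:, :, idx] = xp[:, :, di:di + h, dj:dj + wd]
    y = np.einsum("ock,bckhw->bohw", w, cols, optimize=True)
    y += b[None, :, None, None]
    return y, cols


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray):
    """Gradients of a 3x3 'same' convolution; returns (dx, dw, db)."""
    dw = np.einsum("bohw,bckhw->ock", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    bsz, cin, _, h, wd = cols.shape
    tmp = np.einsum("ock,bohw->bckhw", w, dy, optimize=True)
    dxp = np.zeros((bsz, cin, h + 2, wd + 2), dtype=dy.dtype)
    for idx, (di, dj) in enumerate(_OFFSETS3):
        dxp[:, :, di:di + h, dj:dj + wd] += tmp[:, :, idx]
    return dxp[:, :, 1:-1, 1:-1], dw, db


class DenoiserModel:
    """Tiny convolutional regressor mapping neighbor frames to a prediction
    of the center frame.

    Layers: conv(n_inputs->c) -> ReLU -> [conv(c->c) -> ReLU]* -> conv(c->1).
    The final layer is zero-initialized so the untrained prediction is 0
    (predict-nothing), a safe starting point for contrast-scale data.
    """

    def __init__(self, config: DenoiserConfig):
        self.config = config
        self.scale = 1.0
        self.loss_history: list[float] = []
        rng = np.random.default_rng(config.seed)
        c = config.channels
        n_in = len(config.offsets)
        dims = [n_in] + [c] * (config.depth - 1) + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i, (ci, co) in enumerate(zip(dims[:-1], dims[1:])):
            if i == len(dims) - 2:
                w = np.zeros((co, ci, 9))
            else:
                w = rng.standard_normal((co, ci, 9)) * np.sqrt(2.0 / (ci * 9))
            self.weights.append(w)
            self.biases.append(np.zeros(co))

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def _forward(self, x: np.ndarray, keep: bool = False):
        caches = []
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            y, cols = _conv_forward(h, w, b)
            if i < last:
                mask = y > 0
                h = y * mask
            else:
                mask = None
                h = y
            if keep:
                caches.append((cols, mask))
        return h, caches

    def _backward(self, dy: np.ndarray, caches):
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            cols, _mask = caches[i]
            dy, dw, db = _conv_backward(dy, cols, self.weights[i])
            grads_w.append(dw)
            grads_b.append(db)
            if i > 0:
                dy = dy * caches[i - 1][1]
        return grads_w[::-1], grads_b[::-1]

    def predict(self, neighbor_frames: np.ndarray) -> np.ndarray:
        """Predict the center frame from its neighbors.

        ``neighbor_frames``: (n_inputs, H, W) in stack (contrast) units, in
        the order of ``config.offsets``.
        """
        x = np.nan_to_num(np.asarray(neighbor_frames, dtype=np.float64))
        x = x[None] / self.scale
        y, _ = self._forward(x)
        return y[0, 0] * self.scale


def train_denoiser(ratio_stack: RatiometricStack | np.ndarray,
                   config: DenoiserConfig) -> DenoiserModel:
    """Train the self-supervised neighbor-prediction denoiser.

    Training pairs are random spatial patches of random triplets
    ``(t + o for o in offsets) -> t`` drawn from the stack itself; the loss
    is mean-squared prediction error.  Inputs and targets are scaled by the
    stack RMS for optimizer conditioning.  Fully seeded.
    """
    data = ratio_stack.data if isinstance(ratio_stack, RatiometricStack) else np.asarray(ratio_stack)
    data = np.asarray(data, dtype=np.float64)
    offs = np.array(config.offsets)
    lo, hi = max(0, -offs.min()), data.shape[0] - max(0, offs.max())
    valid_t = np.arange(lo, hi)
    if valid_t.size < 50:
        raise ValueError(
            f"stack supports only {valid_t.size} training triplets; need >= 50")

    model = DenoiserModel(config)
    finite = np.isfinite(data)
    rms = float(np.sqrt(np.mean(data[finite] ** 2))) if finite.any() else 1.0
    model.scale = rms if rms > 0 else 1.0

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7261]))
    h, w = data.shape[1], data.shape[2]
    p = min(config.patch_size, h, w)
    clean = np.nan_to_num(data) / model.scale

    # Adam state
    mw = [np.zeros_like(x) for x in model.weights]
    vw = [np.zeros_like(x) for x in model.weights]
    mb = [np.zeros_like(x) for x in model.biases]
    vb = [np.zeros_like(x) for x in model.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr = config.learning_rate

    for _epoch in range(config.epochs):
        epoch_loss = 0.0
        for _batch in range(config.batches_per_epoch):
            ts = rng.choice(valid_t, size=config.batch_size)
            r0 = rng.integers(0, h - p + 1, size=config.batch_size)
            c0 = rng.integers(0, w - p + 1, size=config.batch_size)
            xb = np.empty((config.batch_size, len(offs), p, p))
            yb = np.empty((config.batch_size, 1, p, p))
            for i in range(config.batch_size):
                sl = np.s_[r0[i]:r0[i] + p, c0[i]:c0[i] + p]
                for j, o in enumerate(offs):
                    xb[i, j] = clean[ts[i] + o][sl]
                yb[i, 0] = clean[ts[i]][sl]
            pred, caches = model._forward(xb, keep=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            epoch_loss += loss
            dy = 2.0 * err / err.size
            gw, gb = model._backward(dy, caches)
            step += 1
            corr = np.sqrt(1 - b2**step) / (1 - b1**step)
            for i in range(len(model.weights)):
                mw[i] = b1 * mw[i] + (1 - b1) * gw[i]
                vw[i] = b2 * vw[i] + (1 - b2) * gw[i] ** 2
                model.weights[i] -= lr * corr * mw[i] / (np.sqrt(vw[i]) + eps)
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                model.biases[i] -= lr * corr * mb[i] / (np.sqrt(vb[i]) + eps)
        model.loss_history.append(epoch_loss / config.batches_per_epoch)
    return model


def residual_map(model: DenoiserModel, ratio_stack: RatiometricStack | np.ndarray,
                 t: int) -> np.ndarray:
    """Residual of frame t against its neighbor-based prediction.

    ``residual = frame_t - model(frames at t + offsets)``.  Structure present
    in the neighbors (static background, slow drift) is subtracted away;
    a transient landing PSF at t survives at close to full contrast.
    """
    data = ratio_stack.data if isinstance(ratio_stack, RatiometricStack) else np.asarray(ratio_stack)
    offs = model.config.offsets
    if t + min(offs) < 0 or t + max(offs) >= data.shape[0]:
        raise ValueError(f"frame {t} with offsets {offs} outside stack of "
                         f"{data.shape[0]} frames")
    neighbors = np.stack([np.asarray(data[t + o], float) for o in offs])
    pred = model.predict(neighbors)
    return np.asarray(data[t], float) - pred


def smooth_residual(residual: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Matched-filter the signed residual with the instrument PSF.

    The residual background is dominated by temporally unpredictable shot
    noise, which is spatially white, whereas a real event is PSF-shaped;
    Gaussian smoothing at the PSF scale is the matched filter and raises
    event-to-background contrast by roughly the square root of the PSF area.
    Linear, so downstream rank maps stay scale-invariant.
    """
    filled = np.nan_to_num(np.asarray(residual, float))
    out = ndimage.gaussian_filter(filled, psf_sigma, mode="nearest")
    out[~np.isfinite(np.asarray(residual, float))] = np.nan
    return out


def probability_map(residual: np.ndarray, t: int = 0,
                    normalization: str = "rank",
                    mask: np.ndarray | None = None) -> ProbabilityMap:
    """Normalize residual magnitudes onto [0, 1] per-pixel probabilities.

    Default is the rank transform over unmasked pixels: probability
    ``(rank - 0.5) / n`` of |residual|, with average ranks for ties (an
    all-equal residual maps to 0.5 everywhere).  Rank normalization is
    parameter-free, bounded, strictly monotone in |residual| and invariant
    under positive rescaling.
    """
    res = np.asarray(residual, dtype=float)
    if normalization != "rank":
        raise ValueError(f"unknown normalization {normalization!r}")
    keep = np.isfinite(res)
    if mask is not None:
        keep &= np.asarray(mask, bool)
    out = np.full(res.shape, np.nan)
    vals = np.abs(res[keep])
    if vals.size:
        ranks = stats.rankdata(vals, method="average")
        out[keep] = (ranks - 0.5) / vals.size
    return ProbabilityMap(out, frame_index=t,
                          params={"n_pixels": int(vals.size)})


def classify_probability_maps(maps: list[ProbabilityMap] | list[np.ndarray],
                              contamination: float = 0.01, seed: int = 0,
                              n_trees: int = 100,
                              positive_only: bool = True) -> AnomalyMask:
    """Isolation-forest classification of pixels from probability maps.

    Each unmasked pixel contributes one row whose columns are its probability
    values across the supplied maps (typically the analysis frame of interest
    and its neighboring analysis frames).  An event pixel is near the top of
    the ranking in several consecutive maps — a rare corner of the joint
    distribution — and is isolated quickly.  With ``positive_only`` (default)
    flagged pixels must also rank above the median in the center map, since
    the anomalies of interest are high-residual pixels, not quiet ones.
    """
    if len(maps) == 0:
        raise ValueError("need at least one probability map")
    arrays = [m.values if isinstance(m, ProbabilityMap) else np.asarray(m, float)
              for m in maps]
    center_i = len(arrays) // 2
    frame_index = (maps[center_i].frame_index
                   if isinstance(maps[center_i], ProbabilityMap) else center_i)
    keep = np.logical_and.reduce([np.isfinite(a) for a in arrays])
    rows = np.stack([a[keep] for a in arrays], axis=1)

    from .features import FeatureMatrix, iforest_classify  # shared engine

    matrix = FeatureMatrix(values=rows, pixel_index=np.argwhere(keep),
                           columns=[f"map_{i}" for i in range(len(arrays))],
                           frame_index=frame_index, frame_shape=keep.shape)
    result = iforest_classify(matrix, contamination=contamination,
                              n_trees=n_trees, seed=seed)
    mask = result.mask
    if positive_only:
        high = np.zeros_like(mask)
        high[keep] = arrays[center_i][keep] > 0.5
        mask = mask & high
    return AnomalyMask(mask, frame_index, path="dnn",
                       params={"contamination": contamination, "seed": seed,
                               "n_maps": len(arrays),
                               "positive_only": positive_only})
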