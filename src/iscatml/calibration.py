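"""Contrast-to-mass calibration ladder and iSCAT/TIRF coincidence analysis.

The interferometric contrast of a protein is linear in its molecular mass
(polarizability scales with volume at roughly constant protein density), but
the proportionality depends on the optics of each instrument, so mass
photometry needs a calibration ladder: main-mode contrasts of several
reference proteins of known mass, fitted with a straight line.  Per ladder
point, the accuracy is the deviation of the measured point from the fitted
line expressed in kDa, and the precision is the bootstrap CI half-width of
the mode expressed as a percentage of the nominal mass.

The coincidence analysis validates label-free detections against the
fluorescence (TIRF) channel: events are matched by position (and, for
interlaced acquisition, within a frame tolerance), and a pixel-wise product
of the two channels' binary event masks gives the coincidence map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consolidate import DEFAULT_MASK_RADIUS, EventRecord, _disk

__all__ = [
    "MassCalibration",
    "CoincidenceResult",
    "fit_mass_ladder",
    "contrast_to_mass",
    "coincidence",
    "plot_mass_ladder",
]


@dataclass
class MassCalibration:
    """Fitted linear contrast-mass model with per-point quality measures."""

    slope: float            # contrast per kDa
    intercept: float        # contrast
    masses_kda: np.ndarray
    contrasts: np.ndarray
    ci_half_widths: np.ndarray | None
    accuracy_kda: np.ndarray      # (measured - fitted) / slope
    precision_pct: np.ndarray | None  # CI half-width in kDa as % of mass
    rms_deviation: float          # contrast units

    def predict_contrast(self, mass_kda: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(mass_kda, float) + self.intercept


@dataclass
class CoincidenceResult:
    """Per-event coincidence flags and channel yields."""

    iscat_flags: np.ndarray
    tirf_flags: np.ndarray
    product_map: np.ndarray | None
    iscat_yield: float
    tirf_yield: float
    n_coincident: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def fit_mass_ladder(masses_kda, contrasts, ci_half_widths=None) -> MassCalibration:
    """Ordinary least-squares line through the (mass, main-mode contrast)
    ladder points.

    Accuracy per point is the residual converted to mass units,
    ``(measured - fitted) / slope`` (kDa); precision per point is the CI
    half-width converted to kDa and expressed as a percentage of the nominal
    mass.  The intercept is left free: residual background biases the
    baseline and shows up as a small nonzero intercept.
    """
    m = np.asarray(masses_kda, float)
    c = np.asarray(contrasts, float)
    if m.size != c.size or m.size < 2:
        raise ValueError("need >= 2 ladder points")
    if np.unique(m).size < 2:
        raise ValueError("ladder is rank-deficient: need >= 2 distinct masses")
    slope, intercept = np.polyfit(m, c, 1)
    if slope == 0:
        raise ValueError("degenerate ladder: zero slope")
    fitted = slope * m + intercept
    residuals = c - fitted
    accuracy = residuals / slope
    ci = None
    precision = None
    if ci_half_widths is not None:
        ci = np.asarray(ci_half_widths, float)
        precision = (ci / abs(slope)) / m * 100.0
    return MassCalibration(
        slope=float(slope), intercept=float(intercept), masses_kda=m,
        contrasts=c, ci_half_widths=ci, accuracy_kda=accuracy,
        precision_pct=precision,
        rms_deviation=float(np.sqrt(np.mean(residuals**2))))


def contrast_to_mass(calibration: MassCalibration,
                     contrast: float | np.ndarray) -> float | np.ndarray:
    """Invert the linear calibration: mass = (contrast - intercept) / slope."""
    if calibration.slope == 0:
        raise ValueError("calibration slope is zero")
    out = (np.asarray(contrast, float) - calibration.intercept) / calibration.slope
    return float(out) if np.isscalar(contrast) else out


def _event_mask_map(events: list[EventRecord],
                    shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, bool)
    for e in events:
        out |= _disk(shape, e.center, e.mask_radius or DEFAULT_MASK_RADIUS)
    return out


def coincidence(iscat_events: list[EventRecord],
                tirf_events: list[EventRecord],
                match_radius: float = 3.0,
                frame_tolerance: int | None = None,
                frame_shape: tuple[int, int] | None = None) -> CoincidenceResult:
    """Match iSCAT and TIRF event lists on a common pixel grid.

    An iSCAT event is coincident when some TIRF event center lies within
    ``match_radius`` pixels (and, if ``frame_tolerance`` is given — one
    interlace cycle for alternating acquisition — within that many frames).
    Greedy nearest-first one-to-one matching; yields are the coincident
    fraction of each channel.  When ``frame_shape`` is given the pixel-wise
    product of the two channels' binary event-mask images is returned too.
    """
    flags_i = np.zeros(len(iscat_events), bool)
    flags_t = np.zeros(len(tirf_events), bool)
    candidates = []
    for i, ei in enumerate(iscat_events):
        for j, et in enumerate(tirf_events):
            d = np.hypot(ei.row - et.row, ei.col - et.col)
            if d > match_radius:
                continue
            if frame_tolerance is not None:
                if abs(ei.frame_first - et.frame_first) > frame_tolerance:
                    continue
            candidates.append((d, i, j))
    pairs = []
    for d, i, j in sorted(candidates):
        if not flags_i[i] and not flags_t[j]:
            flags_i[i] = flags_t[j] = True
            pairs.append((i, j))
    product = None
    if frame_shape is not None:
        product = (_event_mask_map(iscat_events, frame_shape)
                   & _event_mask_map(tirf_events, frame_shape)).astype(np.uint8)
    n = int(flags_i.sum())
    return CoincidenceResult(
        iscat_flags=flags_i, tirf_flags=flags_t, product_map=product,
        iscat_yield=n / len(iscat_events) if iscat_events else 0.0,
        tirf_yield=n / len(tirf_events) if tirf_events else 0.0,
        n_coincident=n, pairs=pairs)


def plot_mass_ladder(cal: MassCalibration, path: str) -> None:
    """Render the ladder: contrast vs mass with fit, per-point accuracy
    (kDa) and precision (% of mass)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    mm = np.linspace(0, cal.masses_kda.max() * 1.05, 50)
    err = cal.ci_half_widths if cal.ci_half_widths is not None else None
    axes[0].errorbar(cal.masses_kda, cal.contrasts, yerr=err, fmt="o")
    axes[0].plot(mm, cal.predict_contrast(mm), "-")
    axes[0].set_xlabel("mass (kDa)")
    axes[0].set_ylabel("iSCAT contrast")
    axes[1].axhline(0.0, ls="--", color="gray")
    axes[1].plot(cal.masses_kda, cal.accuracy_kda, "o")
    axes[1].set_xlabel("mass (kDa)")
    axes[1].set_ylabel("accuracy (kDa)")
    if cal.precision_pct is not None:
        axes[2].plot(cal.masses_kda, cal.precision_pct, "o")
    axes[2].set_xlabel("mass (kDa)")
    axes[2].set_ylabel("precision (% of mass)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
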