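"""Consolidation of per-frame anomaly masks into distinct landing events.

Anomalous pixels from either detection path are accumulated over the frames
belonging to one temporal detection window into a hot-pixel count image,
which is convolved with the instrument PSF to form a smooth detection
density.  Events are then extracted greedily: take the global density
maximum, refine it to the center of mass within the binary-mask radius,
register the event, zero out its surroundings, repeat until the remaining
maxima are indistinguishable from the density noise floor.  Two detections
count as distinct events only if their binary masks (radius 5 px) do not
overlap, i.e. centers more than twice the mask radius apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import AnomalyMask
from .simulator import DEFAULT_PSF_HWHM, hwhm_to_sigma

__all__ = [
    "EventRecord",
    "accumulate_hot_pixels",
    "psf_convolve",
    "extract_events",
    "group_masks_temporally",
    "consolidate_events",
]

DEFAULT_MASK_RADIUS = 5.0


@dataclass
class EventRecord:
    """One consolidated landing-event detection."""

    event_id: int
    frame_first: int
    frame_last: int
    row: float
    col: float
    mask_radius: float = DEFAULT_MASK_RADIUS
    n_pixels: int = 0
    path: str = "features"
    contrast: float | None = None
    tirf_coincident: bool | None = None
    extra: dict = field(default_factory=dict)

    @property
    def center(self) -> tuple[float, float]:
        return (self.row, self.col)


def accumulate_hot_pixels(masks: list[AnomalyMask] | list[np.ndarray]) -> np.ndarray:
    """Per-pixel count of frames in which the pixel was flagged anomalous."""
    if len(masks) == 0:
        raise ValueError("no masks to accumulate")
    arrays = [m.mask if isinstance(m, AnomalyMask) else np.asarray(m, bool)
              for m in masks]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValueError("masks do not share geometry")
    return np.sum(arrays, axis=0).astype(np.int64)


def psf_convolve(hot_frame: np.ndarray, hwhm: float = DEFAULT_PSF_HWHM) -> np.ndarray:
    """Convolve the hot-pixel image with a Gaussian matching the instrument
    PSF (HWHM 2.5 px by default); preserves total mass up to boundary
    truncation."""
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    return ndimage.gaussian_filter(np.asarray(hot_frame, float),
                                   hwhm_to_sigma(hwhm), mode="constant")


def _disk(shape: tuple[int, int], center: tuple[float, float],
          radius: float) -> np.ndarray:
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def extract_events(density: np.ndarray, mask_radius: float = DEFAULT_MASK_RADIUS,
                   noise_floor: float | None = None) -> list[EventRecord]:
    """Greedy extraction of non-overlapping events from a detection density.

    Stopping rule: maxima below ``noise_floor`` are not events; the default
    floor is median + 3 x 1.4826 x MAD of the density's nonzero support —
    a robust location/scale pair, so that the event peaks themselves (which
    can be numerous on busy stacks) do not drag the floor up.  Ties at the
    maximum break to the lexicographically smallest (row, col).  Registered
    events have pairwise center distance > 2 * mask_radius by construction
    (after registering an event, the density within that distance is
    cleared, enforcing the non-overlap counting rule).
    """
    dens = np.asarray(density, float).copy()
    dens[~np.isfinite(dens)] = 0.0
    if np.any(dens < 0):
        raise ValueError("density must be non-negative")
    support = dens[dens > 0]
    if support.size == 0:
        return []
    if noise_floor is None:
        med = float(np.median(support))
        mad = float(np.median(np.abs(support - med)))
        noise_floor = med + 3.0 * 1.4826 * mad
    events: list[EventRecord] = []
    work = dens.copy()
    for _ in range(dens.size):  # hard bound; loop exits via the floor
        peak = work.max()
        if peak <= noise_floor or peak <= 0:
            break
        # lexicographic tie-break: argmax of C-ordered flat array
        idx = int(np.argmax(work))
        pr, pc = divmod(idx, work.shape[1])
        region = _disk(work.shape, (pr, pc), mask_radius)
        weights = work * region
        total = weights.sum()
        if total > 0:
            rows = np.arange(work.shape[0], dtype=float)[:, None]
            cols = np.arange(work.shape[1], dtype=float)[None, :]
            cr = float((weights * rows).sum() / total)
            cc = float((weights * cols).sum() / total)
        else:
            cr, cc = float(pr), float(pc)
        # the refined center may drift toward an already-registered event;
        # such a candidate belongs to that event's mask and is not counted
        if any(np.hypot(cr - e.row, cc - e.col) <= 2.0 * mask_radius
               for e in events):
            work[region] = 0.0
            continue
        events.append(EventRecord(
            event_id=len(events), frame_first=0, frame_last=0,
            row=cr, col=cc, mask_radius=mask_radius,
            n_pixels=0, extra={"peak_density": float(peak)}))
        # clearing 2R around the center enforces mask disjointness
        work[_disk(work.shape, (cr, cc), 2.0 * mask_radius)] = 0.0
    return events


def group_masks_temporally(masks: list[AnomalyMask],
                           gap: int) -> list[list[AnomalyMask]]:
    """Split a time-ordered mask sequence into detection windows.

    Frames with any flagged pixel are clustered: a silent stretch longer
    than ``gap`` frames (use the DRA window so one landing transient cannot
    be split) starts a new window.  Empty masks are dropped.
    """
    nonempty = [m for m in masks if m.mask.any()]
    nonempty.sort(key=lambda m: m.frame_index)
    groups: list[list[AnomalyMask]] = []
    for m in nonempty:
        if groups and m.frame_index - groups[-1][-1].frame_index <= gap:
            groups[-1].append(m)
        else:
            groups.append([m])
    return groups


def _chunk_group(group: list[AnomalyMask], length: int) -> list[list[AnomalyMask]]:
    """Split one silence-free mask run into windows of ``length`` frames."""
    chunks: list[list[AnomalyMask]] = []
    start = group[0].frame_index
    cur: list[AnomalyMask] = []
    for m in group:
        if m.frame_index - start >= length and cur:
            chunks.append(cur)
            cur = []
            start = m.frame_index
        cur.append(m)
    if cur:
        chunks.append(cur)
    return chunks


def consolidate_events(masks: list[AnomalyMask], gap: int,
                       hwhm: float = DEFAULT_PSF_HWHM,
                       mask_radius: float = DEFAULT_MASK_RADIUS,
                       whole_video: bool = False) -> list[EventRecord]:
    """Full consolidation: temporal grouping, accumulation, convolution,
    extraction, temporal bookkeeping.

    By default hot pixels are accumulated per detection window, so that
    re-landings at the same position in disjoint windows are distinct
    events.  Detection windows are silence-delimited mask runs (gaps longer
    than ``gap`` frames split them) further chunked to at most ``2 * gap``
    frames — one landing transient's width — because anomaly classifiers
    flag a fixed pixel quantile per frame and long recordings therefore
    never fall fully silent.  Duplicate extractions of one transient from
    adjacent chunks are merged (same position within twice the mask radius
    and midpoints within ``2 * gap`` frames), keeping the stronger.
    ``whole_video=True`` accumulates over the entire sequence instead.  An
    event's frame span is the contiguous run of contributing anomalous
    frames around its peak.
    """
    if not masks:
        return []
    if whole_video:
        groups = [sorted((m for m in masks if m.mask.any()),
                         key=lambda m: m.frame_index)]
    else:
        groups = [chunk
                  for g in group_masks_temporally(masks, gap)
                  for chunk in _chunk_group(g, 2 * gap)]
    out: list[EventRecord] = []
    for group in groups:
        if not group:
            continue
        hot = accumulate_hot_pixels(group)
        density = psf_convolve(hot, hwhm)
        for ev in extract_events(density, mask_radius):
            disk = _disk(hot.shape, ev.center, mask_radius)
            # temporal footprint: the contiguous run of frames (around the
            # frame of maximum overlap) in which the event's disk is hot;
            # unrelated flagged pixels wandering through the disk at distant
            # times must not stretch the span
            counts = np.array([int((m.mask & disk).sum()) for m in group])
            if counts.max() == 0:
                first = last = group[0].frame_index
            else:
                peak = int(np.argmax(counts))
                a = peak
                while a > 0 and counts[a - 1] > 0:
                    a -= 1
                b = peak
                while b < len(counts) - 1 and counts[b + 1] > 0:
                    b += 1
                first = group[a].frame_index
                last = group[b].frame_index
            ev.event_id = len(out)
            ev.frame_first = first
            ev.frame_last = last
            ev.n_pixels = int((hot * disk).sum())
            ev.path = group[0].path
            out.append(ev)
    if whole_video:
        return out
    # deduplicate one transient extracted from adjacent chunks
    out.sort(key=lambda e: -e.extra.get("peak_density", 0.0))
    kept: list[EventRecord] = []
    for ev in out:
        mid = 0.5 * (ev.frame_first + ev.frame_last)
        dup = any(
            np.hypot(ev.row - k.row, ev.col - k.col) <= 2.0 * mask_radius
            and abs(mid - 0.5 * (k.frame_first + k.frame_last)) <= 2 * gap
            for k in kept)
        if not dup:
            kept.append(ev)
    kept.sort(key=lambda e: (e.frame_first, e.row, e.col))
    for i, ev in enumerate(kept):
        ev.event_id = i
    return kept
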