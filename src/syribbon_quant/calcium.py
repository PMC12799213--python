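"""Stimulus-locked ΔF/F₀ analysis of Ca²⁺-indicator time series.

Workflow, matching the study's custom procedure: background-subtract the
movie, form a pixelwise ΔF image (mean of the first three stimulus frames
minus the mean of the five pre-stimulus frames), draw 2-µm circular ROIs at
sites with and without reconstituted ribbons (assigned blind, from the
structural channel only), extract per-ROI F(t) and ΔF/F₀ traces, summarize
each ROI by ΔF_max/F₀ (mean ΔF/F₀ over the three frames at the
within-stimulus peak), and compare the two ROI classes across cells with a
paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .image import TimeSeries
from .spots import SpotSurface

__all__ = [
    "StimulusProtocol",
    "FluorescenceTrace",
    "background_subtract_timeseries",
    "compute_dF_image",
    "roi_trace",
    "dFmax_over_F0",
    "assign_roi_classes",
    "compare_roi_groups",
]

WITH = "with_syribbon"
WITHOUT = "without_syribbon"


@dataclass
class StimulusProtocol:
    """Frame indices of the depolarization-locked acquisition.

    Defaults encode the study's design: a 500 ms pulse imaged at 20 Hz
    (10 stimulus frames), 5 baseline frames, ΔF from 3 stimulus frames.
    """

    onset_frame: int = 10
    duration_frames: int = 10
    pre_frames: int = 5
    stim_avg_frames: int = 3

    def __post_init__(self) -> None:
        if self.onset_frame < self.pre_frames:
            raise ValueError("onset_frame must leave room for the baseline frames")
        if self.duration_frames < self.stim_avg_frames:
            raise ValueError("stimulus must span at least stim_avg_frames frames")


@dataclass
class FluorescenceTrace:
    """Per-ROI fluorescence trace and its ΔF/F₀ summary."""

    roi_id: int
    roi_center: tuple[float, float]     # (x, y) µm
    roi_diameter: float                 # µm
    f: np.ndarray                       # F(t), a.u.
    f0: float
    dff: np.ndarray                     # (F − F₀)/F₀
    cell_id: int = 0
    roi_class: str | None = None        # WITH | WITHOUT
    dfmax_over_f0: float | None = None
    frames_used: tuple[int, ...] = ()
    valid: bool = True


def background_subtract_timeseries(
    ts: TimeSeries,
    background_roi: tuple[slice, slice] | None = None,
    method: str = "roi",
    ball_radius_px: int = 25,
) -> TimeSeries:
    """Remove camera/ambient background from every frame.

    Default: subtract the per-frame mean of a designated cell-free region
    (``background_roi`` as (row-slice, col-slice)).  ``method="rolling_ball"``
    instead subtracts a per-frame grayscale-opening background estimate.
    Results are clipped at zero.
    """
    data = ts.data.astype(float)
    if method == "roi":
        if background_roi is None:
            raise ValueError("background_roi required for the ROI method")
        bg = data[(slice(None),) + tuple(background_roi)].mean(axis=(1, 2))
        out = np.clip(data - bg[:, None, None], 0, None)
    elif method == "rolling_ball":
        from skimage.morphology import disk

        footprint = disk(ball_radius_px)
        out = np.empty_like(data)
        for t in range(data.shape[0]):
            out[t] = np.clip(data[t] - ndi.grey_opening(data[t], footprint=footprint), 0, None)
    else:
        raise ValueError(f"unknown background method {method!r}")
    return TimeSeries(out, ts.pixel_size_yx, ts.frame_rate)


def compute_dF_image(
    ts: TimeSeries, protocol: StimulusProtocol, smoothed: bool = False
) -> np.ndarray:
    """Pixelwise ΔF: mean of the first ``stim_avg_frames`` stimulus frames
    minus the mean of the ``pre_frames`` baseline frames.

    ``smoothed=True`` returns a 3×3 unweighted-mean copy — display only; all
    quantification uses the raw ΔF.
    """
    o = protocol.onset_frame
    if o + protocol.stim_avg_frames > ts.n_frames or o - protocol.pre_frames < 0:
        raise ValueError("protocol frame indices fall outside the series")
    stim = ts.data[o:o + protocol.stim_avg_frames].mean(axis=0)
    base = ts.data[o - protocol.pre_frames:o].mean(axis=0)
    df = stim - base
    if smoothed:
        df = ndi.uniform_filter(df, size=3, mode="constant")
    return df


def _disc_mask(shape, pixel_size_yx, center_xy, diameter):
    dy, dx = pixel_size_yx
    yy, xx = np.indices(shape)
    cy_px = center_xy[1] / dy - 0.5
    cx_px = center_xy[0] / dx - 0.5
    # pixel-center membership in the physical circle
    return ((yy - cy_px) * dy) ** 2 + ((xx - cx_px) * dx) ** 2 <= (diameter / 2) ** 2


def roi_trace(
    ts: TimeSeries,
    center_xy: tuple[float, float],
    protocol: StimulusProtocol,
    diameter: float = 2.0,
    roi_id: int = 0,
    cell_id: int = 0,
) -> FluorescenceTrace:
    """Extract F(t), F₀ and ΔF/F₀ for one circular ROI (default 2 µm).

    F₀ is the mean of the pre-stimulus baseline frames of the ROI-mean trace.
    A non-positive F₀ flags the trace invalid rather than raising.
    """
    dy, dx = ts.pixel_size_yx
    r = diameter / 2
    h, w = ts.data.shape[1:]
    if (center_xy[0] - r < 0 or center_xy[1] - r < 0
            or center_xy[0] + r > w * dx or center_xy[1] + r > h * dy):
        raise ValueError("ROI extends outside the frame")
    mask = _disc_mask((h, w), ts.pixel_size_yx, center_xy, diameter)
    f = ts.data[:, mask].mean(axis=1)
    o = protocol.onset_frame
    f0 = float(f[o - protocol.pre_frames:o].mean())
    if f0 <= 0:
        return FluorescenceTrace(
            roi_id=roi_id, roi_center=tuple(center_xy), roi_diameter=diameter,
            f=f, f0=f0, dff=np.zeros_like(f), cell_id=cell_id, valid=False,
        )
    return FluorescenceTrace(
        roi_id=roi_id, roi_center=tuple(center_xy), roi_diameter=diameter,
        f=f, f0=f0, dff=(f - f0) / f0, cell_id=cell_id,
    )


def dFmax_over_F0(trace: FluorescenceTrace, protocol: StimulusProtocol) -> FluorescenceTrace:
    """ΔF_max/F₀: mean ΔF/F₀ over the three frames at the stimulus peak.

    The peak is the argmax of ΔF/F₀ within the stimulus window; the averaged
    frames are [t_peak, t_peak+2] clipped to the window (onset-locked
    fallback when the argmax sits in the last two window frames).
    """
    if not trace.valid:
        raise ValueError("cannot summarize an invalid trace (F0 <= 0)")
    o, d, k = protocol.onset_frame, protocol.duration_frames, protocol.stim_avg_frames
    window = trace.dff[o:o + d]
    t_peak = o + int(np.argmax(window))
    if t_peak + k > o + d:
        t_peak = o + d - k
    frames = tuple(range(t_peak, t_peak + k))
    value = float(trace.dff[list(frames)].mean())
    out = replace(trace)
    out.dfmax_over_f0 = value
    out.frames_used = frames
    return out


def assign_roi_classes(
    roi_centers_xy: list[tuple[float, float]],
    syribbon_spots: list[SpotSurface] | list[np.ndarray],
    structural_image: np.ndarray,
    pixel_size_yx: tuple[float, float],
    roi_diameter: float = 2.0,
) -> list[str]:
    """Classify each ROI as with/without a ribbon from the structural channel.

    An ROI is ``with_syribbon`` iff its disc overlaps any ribbon spot mask in
    the structural (e.g. RIBEYE-GFP) image.  The API deliberately accepts
    only the structural channel, enforcing the study's blinding: class
    assignment never sees the indicator signal.
    """
    shape = structural_image.shape
    spot_mask = np.zeros(shape, dtype=bool)
    for s in syribbon_spots:
        if isinstance(s, SpotSurface):
            # project the spot's voxels onto the imaging plane
            for v in s.voxels:
                if 0 <= v[1] < shape[0] and 0 <= v[2] < shape[1]:
                    spot_mask[v[1], v[2]] = True
        else:
            spot_mask |= np.asarray(s, dtype=bool)
    classes = []
    for c in roi_centers_xy:
        disc = _disc_mask(shape, pixel_size_yx, c, roi_diameter)
        classes.append(WITH if np.any(disc & spot_mask) else WITHOUT)
    return classes


def compare_roi_groups(traces: list[FluorescenceTrace]) -> dict:
    """Paired comparison of ΔF_max/F₀ between ROI classes across cells.

    Per cell, ΔF_max/F₀ is averaged within each class; the with/without
    differences are tested with a two-sided paired t-test across cells.
    Percent difference is ``mean(with/without − 1) × 100``.  Every cell must
    contribute at least one ROI of each class, and at least two cells are
    needed for the test.
    """
    rows = [
        {"cell_id": t.cell_id, "roi_class": t.roi_class, "value": t.dfmax_over_f0}
        for t in traces
        if t.valid and t.roi_class in (WITH, WITHOUT) and t.dfmax_over_f0 is not None
    ]
    if not rows:
        raise ValueError("no classified, summarized traces to compare")
    df = pd.DataFrame(rows)
    per_cell = df.groupby(["cell_id", "roi_class"])["value"].mean().unstack()
    if WITH not in per_cell or WITHOUT not in per_cell or per_cell.isna().any().any():
        raise ValueError("every cell must contribute at least one ROI of each class")
    if len(per_cell) < 2:
        raise ValueError("paired test undefined for a single cell")
    w = per_cell[WITH].to_numpy()
    wo = per_cell[WITHOUT].to_numpy()
    if np.allclose(w, wo):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(w, wo)
    return {
        "per_cell": per_cell,
        "mean_with": float(w.mean()),
        "sem_with": float(w.std(ddof=1) / np.sqrt(len(w))) if len(w) > 1 else 0.0,
        "mean_without": float(wo.mean()),
        "sem_without": float(wo.std(ddof=1) / np.sqrt(len(wo))) if len(wo) > 1 else 0.0,
        "mean_difference": float((w - wo).mean()),
        "percent_difference": float(np.mean(w / wo - 1.0) * 100.0),
        "t": float(t_stat),
        "p": float(p),
        "n_cells": int(len(per_cell)),
    }
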