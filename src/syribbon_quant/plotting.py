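"""Publication-style figure panels.

Box plots follow the convention used throughout the study's figures: a cross
at the mean, a band at the median, box at the 25/75 percentiles, whiskers at
the 10/90 percentiles, and the individual points overlaid.  Functions return
the glyph data they plotted so figure content is testable without pixel
comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .stats import descriptives  # noqa: E402

__all__ = ["box_panel", "volume_histogram", "dff_overlay", "iv_curve_panel"]


def box_panel(groups: dict, ax=None, ylabel: str = "", point_alpha: float = 0.5):
    """Mean-cross / median-band / 25-75 box / 10-90 whisker panel.

    Empty groups are skipped with a warning.  Returns ``(ax, glyphs)`` where
    ``glyphs[name]`` holds the plotted percentile positions.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * max(len(groups), 1) + 1, 3))
    glyphs = {}
    pos = 0
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            warnings.warn(f"group {name!r} is empty; panel omitted", stacklevel=2)
            continue
        d = descriptives(v)
        ax.add_patch(
            plt.Rectangle((pos - 0.25, d.p25), 0.5, d.p75 - d.p25,
                          fill=False, edgecolor="k"))
        ax.hlines(d.median, pos - 0.25, pos + 0.25, color="k")
        ax.vlines(pos, d.p10, d.p25, color="k")
        ax.vlines(pos, d.p75, d.p90, color="k")
        ax.hlines([d.p10, d.p90], pos - 0.12, pos + 0.12, color="k")
        ax.scatter([pos], [d.mean], marker="x", color="crimson", zorder=3)
        ax.scatter(pos + rng.uniform(-0.15, 0.15, v.size), v,
                   s=8, alpha=point_alpha, color="gray", zorder=2)
        glyphs[name] = {
            "position": pos, "mean": d.mean, "median": d.median,
            "p10": d.p10, "p25": d.p25, "p75": d.p75, "p90": d.p90,
        }
        pos += 1
    ax.set_xticks(range(len(glyphs)))
    ax.set_xticklabels(list(glyphs))
    ax.set_ylabel(ylabel)
    return ax, glyphs


def volume_histogram(volumes, ax=None, bins=30, label=""):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    counts, edges, _ = ax.hist(np.asarray(volumes, float), bins=bins, label=label,
                               color="steelblue", alpha=0.8)
    ax.set_xlabel("volume (µm³)")
    ax.set_ylabel("count")
    return ax, (counts, edges)


def dff_overlay(traces, protocol=None, ax=None):
    """Overlay ΔF/F₀ traces, colored by ROI class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    colors = {"with_syribbon": "magenta", "without_syribbon": "green", None: "gray"}
    for t in traces:
        ax.plot(t.dff, color=colors.get(t.roi_class, "gray"), alpha=0.6, lw=0.8)
    if protocol is not None:
        ax.axvspan(protocol.onset_frame,
                   protocol.onset_frame + protocol.duration_frames,
                   color="0.9", zorder=0)
    ax.set_xlabel("frame")
    ax.set_ylabel("ΔF/F₀")
    return ax


def iv_curve_panel(curves, labels=None, ax=None, density: bool = True):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = labels or [None] * len(curves)
    for iv, lab in zip(curves, labels):
        y = iv.current_densities if density else iv.currents
        ax.plot(iv.voltages, y, marker="o", ms=3, label=lab)
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("pA/pF" if density else "pA")
    if any(labels):
        ax.legend(frameon=False)
    return ax
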