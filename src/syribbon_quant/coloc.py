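"""Pixel-intensity colocalization and membrane-peripherality measures.

Implements the Coloc-2-style toolkit the study applied inside 1-µm-thick
peripheral ROIs: Pearson correlation, (thresholded) Manders coefficients with
Costes auto-thresholds, the Costes block-scramble significance test (100
repetitions), the periphery:interior intensity ratio, and tangential
line-profile correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu

from .image import ImageStack

__all__ = [
    "CellGeometry",
    "ColocResult",
    "build_cell_geometry",
    "peripheral_ratio",
    "pearson_pixel",
    "manders",
    "costes_thresholds",
    "costes_test",
    "line_profile_correlation",
]


@dataclass
class CellGeometry:
    """Per-plane cell mask split into a peripheral ring and an interior.

    ``ring_mask`` holds the voxels within ``ring_thickness`` µm inside the
    cell boundary; ``interior_mask`` the enclosed remainder.  ``central_planes``
    lists the analysis planes (basal and top plane excluded).
    """

    cell_mask: np.ndarray        # (Z, Y, X) bool
    ring_mask: np.ndarray
    interior_mask: np.ndarray
    central_planes: list[int] = field(default_factory=list)
    ring_thickness: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.ring_mask & self.interior_mask):
            raise ValueError("ring and interior masks must be disjoint")


def build_cell_geometry(
    stack: ImageStack,
    membrane_channel=None,
    cell_mask: np.ndarray | None = None,
    ring_thickness: float = 1.0,
) -> CellGeometry:
    """Derive the peripheral ring and interior from the membrane channel.

    Per plane, the membrane signal is thresholded (Otsu), holes are filled to
    obtain the cell cross-section, and the ring is the inward morphological
    band of the stated physical thickness.  Alternatively a precomputed
    boolean ``cell_mask`` may be supplied (the manual-polygon route).
    An outline that does not close cannot be filled and raises.
    """
    if ring_thickness <= 0:
        raise ValueError("ring_thickness must be positive (empty ring otherwise)")
    dz, dy, dx = stack.voxel_size_zyx
    if cell_mask is None:
        if membrane_channel is None:
            raise ValueError("either membrane_channel or cell_mask is required")
        img = stack.channel(membrane_channel).astype(float)
        if np.ptp(img) == 0:
            raise ValueError("membrane channel is empty")
        thr = threshold_otsu(img)
        shell = img > thr
        cell_mask = np.zeros_like(shell)
        for z in range(shell.shape[0]):
            cell_mask[z] = ndi.binary_fill_holes(shell[z])
            n_shell = shell[z].sum()
            if not n_shell:
                continue
            if cell_mask[z].sum() < 1.5 * n_shell:
                # nothing was filled: fine for a solid polar cap, an error
                # for a thin outline that failed to close
                rows = np.any(shell[z], axis=1).sum()
                cols = np.any(shell[z], axis=0).sum()
                solidity = n_shell / max(rows * cols, 1)
                if solidity < 0.4:
                    raise ValueError(
                        f"open contour in plane {z}: membrane outline did not close"
                    )
    cell_mask = cell_mask.astype(bool)

    ring = np.zeros_like(cell_mask)
    interior = np.zeros_like(cell_mask)
    for z in range(cell_mask.shape[0]):
        plane = cell_mask[z]
        if not plane.any():
            continue
        # inward distance from the boundary, in physical units
        depth = ndi.distance_transform_edt(plane, sampling=(dy, dx))
        ring[z] = plane & (depth <= ring_thickness)
        interior[z] = plane & ~ring[z]

    nonempty = [z for z in range(cell_mask.shape[0]) if cell_mask[z].any()]
    central = nonempty[1:-1] if len(nonempty) >= 3 else []
    if len(central) < 3:
        warnings.warn(
            f"only {len(central)} central plane(s) available; the analysis "
            "convention asks for at least three (basal and top excluded)",
            stacklevel=2,
        )
    return CellGeometry(
        cell_mask=cell_mask,
        ring_mask=ring,
        interior_mask=interior,
        central_planes=central,
        ring_thickness=ring_thickness,
    )


def peripheral_ratio(stack: ImageStack, channel, geometry: CellGeometry) -> float:
    """Mean periphery:interior intensity ratio over the central planes.

    Per plane, ratio = mean(ring) / mean(interior); the cell value is the
    mean over central planes.  Returns NaN when the interior mean is zero
    (undefined), with a warning.
    """
    img = stack.channel(channel).astype(float)
    planes = geometry.central_planes or [
        z for z in range(img.shape[0]) if geometry.cell_mask[z].any()
    ]
    ratios = []
    for z in planes:
        rm, im = geometry.ring_mask[z], geometry.interior_mask[z]
        if not rm.any() or not im.any():
            continue
        inner = img[z][im].mean()
        if inner == 0:
            warnings.warn(f"interior mean is zero in plane {z}; ratio undefined", stacklevel=2)
            return float("nan")
        ratios.append(img[z][rm].mean() / inner)
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# pixel-intensity coefficients


@dataclass
class ColocResult:
    pearson_r: float
    m1: float | None = None
    m2: float | None = None
    costes_p: float | None = None
    n_repetitions: int | None = None
    threshold_a: float | None = None
    threshold_b: float | None = None


def pearson_pixel(img_a: np.ndarray, img_b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation over masked voxel pairs (requires ≥ 10 voxels)."""
    a = np.asarray(img_a, dtype=float)[mask]
    b = np.asarray(img_b, dtype=float)[mask]
    if a.size < 10:
        raise ValueError("need at least 10 masked voxels")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def costes_thresholds(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Costes auto-thresholds via bisection on the channel-A threshold.

    B is regressed on A (least squares); the thresholds are the largest pair
    (T, a·T + c) on the regression line for which the correlation of the
    sub-threshold pixel population is ≤ 0.
    """
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant channel: Costes thresholds undefined")
    slope, inter = np.polyfit(a, b, 1)

    def sub_r(t):
        sel = a < t
        if sel.sum() < 10 or a[sel].std() == 0 or b[sel].std() == 0:
            return -1.0
        return np.corrcoef(a[sel], b[sel])[0, 1]

    lo, hi = float(a.min()), float(a.max())
    if sub_r(hi) <= 0:           # even the full population is uncorrelated
        return hi, slope * hi + inter
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if sub_r(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return lo, slope * lo + inter


def manders(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: np.ndarray,
    thresholds: tuple[float, float] | str = "auto",
) -> tuple[float, float]:
    """Thresholded Manders coefficients.

    M1 = Σ A_i[B_i > t_B] / Σ A_i and symmetrically for M2.  ``"auto"`` uses
    Costes auto-thresholds; a pair of fixed thresholds may be given instead.
    """
    a = np.asarray(img_a, dtype=float)[mask]
    b = np.asarray(img_b, dtype=float)[mask]
    if thresholds == "auto":
        try:
            t_a, t_b = costes_thresholds(a, b)
        except ValueError:
            t_a = t_b = 0.0
    else:
        t_a, t_b = thresholds
        if t_a < 0 or t_b < 0:
            raise ValueError("thresholds must be non-negative")
    sum_a, sum_b = a.sum(), b.sum()
    m1 = float(a[b > t_b].sum() / sum_a) if sum_a > 0 else float("nan")
    m2 = float(b[a > t_a].sum() / sum_b) if sum_b > 0 else float("nan")
    return m1, m2


# ---------------------------------------------------------------------------
# Costes randomization


def _block_grid(shape, block):
    """Slices tiling an array with cubes/squares of side ``block``."""
    ranges = [range(0, s, block) for s in shape]
    out = []
    from itertools import product

    for starts in product(*ranges):
        out.append(tuple(slice(st, min(st + block, s)) for st, s in zip(starts, shape)))
    return out


def costes_test(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: np.ndarray,
    n: int = 100,
    block_size: int = 4,
    rng: np.random.Generator | int | None = None,
) -> ColocResult:
    """Costes block-scramble significance test for colocalization.

    Channel B is partitioned into PSF-scale blocks inside the mask; the block
    contents are permuted ``n`` times and the observed Pearson r is compared
    with the scrambled distribution.  ``costes_p`` is the one-sided fraction
    of scrambles with r ≥ observed (colocalization = high r).
    """
    if n <= 0:
        raise ValueError("n repetitions must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if any(block_size > s for s in mask.shape):
        raise ValueError(f"block size {block_size} exceeds mask extent {mask.shape}")

    blocks = [
        sl for sl in _block_grid(mask.shape, block_size)
        if mask[sl].mean() >= 0.5 and mask[sl].size == block_size ** mask.ndim
    ]
    if len(blocks) < 2:
        raise ValueError("mask too small: fewer than 2 scramble blocks")

    r_obs = pearson_pixel(a, b, mask)
    stacked = np.stack([b[sl] for sl in blocks])
    b_scr = b.copy()
    count = 0
    for _ in range(n):
        perm = rng.permutation(len(blocks))
        for sl, k in zip(blocks, perm):
            b_scr[sl] = stacked[k]
        if pearson_pixel(a, b_scr, mask) >= r_obs:
            count += 1
    m1, m2 = manders(a, b, mask)
    return ColocResult(
        pearson_r=r_obs, m1=m1, m2=m2, costes_p=count / n, n_repetitions=n
    )


# ---------------------------------------------------------------------------
# line profiles


def line_profile_correlation(
    img_a: np.ndarray,
    img_b: np.ndarray,
    polyline: np.ndarray,
    width: int = 3,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Intensity traces along a polyline and their Pearson correlation.

    ``polyline`` is an (N, 2) array of (y, x) pixel vertices.  The polyline is
    resampled at 1-pixel arc-length steps; at each step the intensity is
    averaged over ``width`` samples perpendicular to the local direction.
    Returns ``(trace_a, trace_b, r)``; r is NaN for constant traces.
    """
    if width < 1:
        raise ValueError("width must be >= 1 pixel")
    pl = np.asarray(polyline, dtype=float)
    if pl.ndim != 2 or pl.shape[0] < 2 or pl.shape[1] != 2:
        raise ValueError("polyline must be (N>=2, 2) of (y, x) vertices")
    for im in (img_a, img_b):
        if (pl[:, 0].min() < 0 or pl[:, 1].min() < 0
                or pl[:, 0].max() > im.shape[0] - 1 or pl[:, 1].max() > im.shape[1] - 1):
            raise ValueError("polyline extends outside the image")

    # resample at unit arc length
    seg = np.diff(pl, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, arc[-1] + 1e-9, 1.0)
    ys = np.interp(s, arc, pl[:, 0])
    xs = np.interp(s, arc, pl[:, 1])
    # local tangent and unit normal
    ty = np.gradient(ys)
    tx = np.gradient(xs)
    tlen = np.hypot(ty, tx)
    tlen[tlen == 0] = 1.0
    ny_, nx_ = -tx / tlen, ty / tlen
    offsets = np.arange(width) - (width - 1) / 2.0

    def trace(im):
        vals = np.empty((len(offsets), len(s)))
        for i, o in enumerate(offsets):
            coords = np.vstack([ys + o * ny_, xs + o * nx_])
            vals[i] = ndi.map_coordinates(
                np.asarray(im, dtype=float), coords, order=1, mode="nearest"
            )
        return vals.mean(axis=0)

    ta, tb = trace(img_a), trace(img_b)
    if ta.std() == 0 or tb.std() == 0:
        return ta, tb, float("nan")
    r = float(np.corrcoef(ta, tb)[0, 1])
    return ta, tb, r
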