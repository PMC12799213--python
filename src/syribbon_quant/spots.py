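"""3D punctum segmentation, morphometry and proximity classification.

Replaces the proprietary surface-detection stage with a deterministic
pipeline: per-plane rolling-ball background subtraction, Gaussian smoothing
at the surface-detail scale (0.16 µm), thresholding (Otsu by default),
connected-component labeling, a ≥10-voxel size filter and per-component
morphometry.

Morphometry reports volume (voxel count × voxel volume), surface area from a
marching-cubes isosurface whose facet areas are projected onto smoothed-field
normals (this removes the voxel staircase without shrinking planar faces),
and Wadell sphericity Ψ = π^{1/3}(6V)^{2/3}/A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .image import ImageStack

__all__ = [
    "DetectionParams",
    "SpotSurface",
    "subtract_background",
    "detect_spots",
    "measure_spot",
    "measure_mask",
    "filter_spots",
    "surface_distance",
    "classify_by_proximity",
    "ProximityResult",
    "volume_correlation",
    "spots_to_frame",
    "voxel_face_area",
]

#: background-subtraction ball diameters (µm) used per marker in the study
DEFAULT_BACKGROUND_DIAMETERS = {"RIBEYE": 0.3, "Bassoon": 0.1, "CaV1.3": 0.08}


@dataclass
class DetectionParams:
    """Tunable segmentation settings.

    surface_detail is the Gaussian smoothing scale (µm, σ) applied before
    thresholding; ``threshold_method`` is ``"otsu"`` or an absolute intensity.
    """

    surface_detail: float = 0.16
    background_sphere_diameter: float | dict = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_DIAMETERS)
    )
    threshold_method: str | float = "otsu"
    min_voxels: int = 10
    volume_bounds: tuple[float, float] = (0.02, 2.0)
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.volume_bounds[0] >= self.volume_bounds[1]:
            raise ValueError("volume_bounds must satisfy min < max")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def ball_diameter(self, channel: str) -> float | None:
        d = self.background_sphere_diameter
        if isinstance(d, dict):
            return d.get(channel)
        return d


@dataclass
class SpotSurface:
    """One segmented punctum with its morphometry."""

    id: int
    channel: str
    voxel_count: int
    volume: float                      # µm³
    surface_area: float                # µm²
    sphericity: float
    centroid: tuple[float, float, float]   # (z, y, x) µm
    voxels: np.ndarray                 # (N, 3) int, (z, y, x)
    boundary_voxels: np.ndarray        # (M, 3) int
    voxel_size_zyx: tuple[float, float, float]
    colocalized: bool = False
    partner_id: int | None = None

    @property
    def centroid_xyz(self) -> tuple[float, float, float]:
        z, y, x = self.centroid
        return (x, y, z)


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(
    stack: ImageStack, channel, sphere_diameter: float
) -> np.ndarray:
    """Rolling-ball background subtraction, applied per z-plane.

    Background is estimated as a grayscale opening with a flat disk of the
    stated physical diameter (structures smaller than the ball survive the
    subtraction essentially intact).  Negative residuals are clipped to zero.
    A ball smaller than one pixel cannot remove anything: the image is
    returned unchanged with a warning.
    """
    if sphere_diameter <= 0:
        raise ValueError("sphere_diameter must be positive")
    img = stack.channel(channel).astype(float)
    dx = stack.voxel_size_zyx[2]
    radius_px = int(round(sphere_diameter / 2.0 / dx))
    if radius_px < 1:
        warnings.warn(
            f"background ball diameter {sphere_diameter} µm is below one pixel "
            f"({dx} µm); skipping subtraction",
            stacklevel=2,
        )
        return img
    footprint = morphology.disk(radius_px)
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        background = ndi.grey_opening(img[z], footprint=footprint)
        out[z] = np.clip(img[z] - background, 0, None)
    return out


# ---------------------------------------------------------------------------
# morphometry


def _projected_mesh_area(
    mask: np.ndarray, spacing: tuple[float, float, float], normal_sigma_vox: float = 1.0
) -> float:
    """Surface area of a binary mask, staircase-corrected.

    Marching-cubes facet areas are projected onto the local normal of a
    Gaussian-smoothed copy of the mask: exact for axis-aligned planar faces
    (no shrinkage) and removes the ~9% staircase overestimate on spheres.
    """
    m = np.pad(mask, 2)
    if m.sum() == 0:
        return 0.0
    try:
        verts, faces, _, _ = measure.marching_cubes(
            m.astype(np.uint8), level=0.5, spacing=spacing
        )
    except (ValueError, RuntimeError):
        return voxel_face_area(mask, spacing)
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    u = ndi.gaussian_filter(m.astype(float), normal_sigma_vox)
    grads = np.gradient(u, *spacing)
    cent_vox = tri.mean(axis=1) / np.asarray(spacing)
    nvec = np.stack(
        [ndi.map_coordinates(g, cent_vox.T, order=1) for g in grads], axis=1
    )
    norm = np.linalg.norm(nvec, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    nvec /= norm
    return float(np.abs((cross * nvec).sum(axis=1)).sum() / 2.0)


def voxel_face_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Brute-force surface area: summed areas of exposed voxel faces.

    Kept as the independent oracle; known to overestimate the area of smooth
    surfaces (biases Ψ low), never used by the main path.
    """
    dz, dy, dx = spacing
    face_areas = (dy * dx, dz * dx, dz * dy)
    m = np.pad(mask.astype(np.int8), 1)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.abs(np.diff(m, axis=axis))
        total += fa * diff.sum()
    return float(total)


def measure_mask(
    mask: np.ndarray, voxel_size_zyx: tuple[float, float, float]
) -> tuple[float, float, float, tuple[float, float, float]]:
    """(volume µm³, surface area µm², Wadell Ψ, centroid (z,y,x) µm) of a binary mask."""
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty mask")
    dz, dy, dx = voxel_size_zyx
    volume = count * dz * dy * dx
    area = _projected_mesh_area(mask, voxel_size_zyx)
    psi = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area if area > 0 else np.nan
    idx = np.argwhere(mask)
    centroid = ((idx[:, 0].mean() + 0.5) * dz, (idx[:, 1].mean() + 0.5) * dy,
                (idx[:, 2].mean() + 0.5) * dx)
    return volume, area, psi, centroid


def measure_spot(label_map: np.ndarray, label: int, voxel_size_zyx):
    """Morphometry of one labeled component; raises if the label is absent."""
    mask = label_map == label
    if not mask.any():
        raise ValueError(f"label {label} not present in label map")
    return measure_mask(mask, tuple(voxel_size_zyx))


_STRUCTS = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=_STRUCTS[6], border_value=0)
    return np.argwhere(mask & ~eroded)


# ---------------------------------------------------------------------------
# detection


def detect_spots(
    stack: ImageStack,
    channel,
    params: DetectionParams | None = None,
    subtract_bg: bool = True,
) -> list[SpotSurface]:
    """Segment one channel into puncta, sorted by descending volume.

    Pipeline: background subtraction → Gaussian smoothing at the
    surface-detail scale → threshold → connected components → size filter →
    morphometry.  An all-zero channel yields an empty list.
    """
    params = params or DetectionParams()
    ch_name = stack.channels[stack.channel_index(channel)]
    ball = params.ball_diameter(ch_name)
    if subtract_bg and ball:
        img = subtract_background(stack, channel, ball)
    else:
        img = stack.channel(channel).astype(float)
    if not np.any(img):
        return []

    if params.surface_detail > 0:
        sigma = [params.surface_detail / v for v in stack.voxel_size_zyx]
        img = ndi.gaussian_filter(img, sigma)

    if params.threshold_method == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold_method)
    binary = img > thr
    if not binary.any():
        return []

    label_map, n = ndi.label(binary, structure=_STRUCTS[params.connectivity])
    spots = []
    for lab in range(1, n + 1):
        mask = label_map == lab
        count = int(mask.sum())
        if count < params.min_voxels:
            continue
        volume, area, psi, centroid = measure_mask(mask, stack.voxel_size_zyx)
        spots.append(
            SpotSurface(
                id=-1,
                channel=ch_name,
                voxel_count=count,
                volume=volume,
                surface_area=area,
                sphericity=psi,
                centroid=centroid,
                voxels=np.argwhere(mask),
                boundary_voxels=_boundary(mask),
                voxel_size_zyx=stack.voxel_size_zyx,
            )
        )
    spots.sort(key=lambda s: -s.volume)
    for i, s in enumerate(spots):
        s.id = i
    return spots


def filter_spots(
    spots: list[SpotSurface], volume_bounds: tuple[float, float] = (0.02, 2.0)
) -> tuple[list[SpotSurface], list[tuple[SpotSurface, str]]]:
    """Split spots into kept and rejected by inclusive volume bounds.

    Structures above 2 µm³ are usually cytosolic aggregates; below 0.02 µm³,
    unresolvable specks.  Idempotent by construction.
    """
    lo, hi = volume_bounds
    kept, rejected = [], []
    for s in spots:
        if s.volume < lo:
            rejected.append((s, "too_small"))
        elif s.volume > hi:
            rejected.append((s, "too_large"))
        else:
            kept.append(s)
    return kept, rejected


# ---------------------------------------------------------------------------
# distances and proximity classes


def surface_distance(a: SpotSurface, b: SpotSurface) -> float:
    """Minimum boundary-to-boundary Euclidean distance in µm (0 if overlapping)."""
    if a.voxel_size_zyx != b.voxel_size_zyx:
        raise ValueError("spots must share a voxel grid")
    av = {tuple(v) for v in a.voxels}
    if any(tuple(v) in av for v in b.voxels):
        return 0.0
    scale = np.asarray(a.voxel_size_zyx)
    pa = a.boundary_voxels * scale
    pb = b.boundary_voxels * scale
    tree = cKDTree(pb)
    d, _ = tree.query(pa, k=1)
    return float(d.min())


@dataclass
class ProximityResult:
    """Outcome of distance-threshold classification of query spots."""

    paired: list[tuple[int, int, float]]       # (query_id, reference_id, distance)
    unpaired: list[int]
    threshold: float

    @property
    def n_paired(self) -> int:
        return len(self.paired)

    def partner_of(self, query_id: int) -> int | None:
        for q, r, _ in self.paired:
            if q == query_id:
                return r
        return None


def classify_by_proximity(
    query_spots: list[SpotSurface],
    reference_spots: list[SpotSurface],
    threshold: float,
) -> ProximityResult:
    """Pair each query spot with its nearest reference iff within threshold.

    This realizes the study's two proximity classes: colocalization of
    RIBEYE with Bassoon surfaces at ≤0.06 µm, and the stricter ≤0.045 µm
    class used to call Ca_V clusters ribbon-associated.  Ties are broken by
    the smaller reference id.  Query spots are annotated in place
    (``colocalized``, ``partner_id``).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    paired, unpaired = [], []
    for q in query_spots:
        best = None
        for r in reference_spots:
            d = surface_distance(q, r)
            if best is None or d < best[1] or (d == best[1] and r.id < best[0]):
                best = (r.id, d)
        if best is not None and best[1] <= threshold:
            q.colocalized, q.partner_id = True, best[0]
            paired.append((q.id, best[0], best[1]))
        else:
            q.colocalized, q.partner_id = False, None
            unpaired.append(q.id)
    return ProximityResult(paired=paired, unpaired=unpaired, threshold=threshold)


def volume_correlation(
    paired: list[tuple[SpotSurface, SpotSurface]]
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between volumes of paired spots."""
    if len(paired) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    va = [a.volume for a, _ in paired]
    vb = [b.volume for _, b in paired]
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# tabular export


def spots_to_frame(spots: list[SpotSurface]) -> pd.DataFrame:
    """Per-spot CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "channel": s.channel,
                "voxel_count": s.voxel_count,
                "volume_um3": s.volume,
                "surface_area_um2": s.surface_area,
                "sphericity": s.sphericity,
                "centroid_z_um": s.centroid[0],
                "centroid_y_um": s.centroid[1],
                "centroid_x_um": s.centroid[2],
                "colocalized": s.colocalized,
                "partner_id": s.partner_id,
            }
            for s in spots
        ]
    )


def summarize_spots(spots: list[SpotSurface]) -> dict:
    """Per-cell summary: count, mean ± SD and CV of volume, mean Ψ."""
    vols = np.array([s.volume for s in spots])
    psis = np.array([s.sphericity for s in spots])
    if len(vols) == 0:
        return {"n_spots": 0}
    mean_v = vols.mean()
    sd_v = vols.std(ddof=1) if len(vols) > 1 else 0.0
    return {
        "n_spots": len(vols),
        "volume_mean_um3": float(mean_v),
        "volume_sd_um3": float(sd_v),
        "volume_cv": float(sd_v / mean_v) if mean_v > 0 else np.nan,
        "sphericity_mean": float(psis.mean()),
        "sphericity_sd": float(psis.std(ddof=1)) if len(psis) > 1 else 0.0,
    }
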