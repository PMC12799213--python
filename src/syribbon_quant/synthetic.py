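"""Seeded, ground-truth-annotated simulators for every pipeline input.

Three generators emulate the study's data:

* :func:`generate_cell_stack` — a multi-channel confocal-like 3D stack of an
  ellipsoidal cell: a membrane-shell channel plus membrane-anchored punctum
  pairs/triples (RIBEYE-like, Bassoon-like, Ca_V-like) and cytosolic puncta,
  rendered analytically with sub-voxel antialiasing, Gaussian-PSF blur and
  Poisson + Gaussian noise.
* :func:`generate_timeseries` — a single-plane spinning-disk-like Ca²⁺
  indicator movie with baseline, a stimulus-evoked transient at hotspot sites
  and an optional diffuse membrane component.
* :func:`generate_iv_recording` — whole-cell voltage-clamp sweeps following a
  Boltzmann-gated ohmic model with linear leak, plus p/10 leak pulses.

Every generator is deterministic for a fixed (config, seed) and returns the
ground truth alongside the data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image import ImageStack, TimeSeries
from .ephys import IVRecording

__all__ = [
    "NoiseModel",
    "SimConfig",
    "GroundTruthSpot",
    "GroundTruthTransient",
    "generate_cell_stack",
    "generate_timeseries",
    "generate_iv_recording",
    "place_membrane_spot",
    "place_cytosolic_spot",
    "random_syribbon_spots",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
    "ellipsoid_sphericity",
    "write_ground_truth",
]


@dataclass
class NoiseModel:
    """Photon-counting + camera read noise.

    ``out = offset + gain * Poisson(signal / gain) + Normal(0, read_sigma)``.
    ``gain`` is the a.u.-per-photon conversion; with ``enabled=False`` the
    signal passes through untouched (plus offset).
    """

    gain: float = 2.0
    read_sigma: float = 2.0
    offset: float = 0.0
    enabled: bool = True

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.enabled:
            return signal + self.offset
        out = self.gain * rng.poisson(np.clip(signal, 0, None) / self.gain)
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=signal.shape)
        return out + self.offset


@dataclass
class SimConfig:
    """Geometry and acquisition settings for the simulated cell.

    All user-facing coordinates are (x, y, z) in µm; arrays are (z, y, x).
    Defaults reproduce the acquisition grid of the study: 80 × 80 nm pixels,
    200 nm z-step.
    """

    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2)   # (dx, dy, dz) µm
    stack_shape: tuple[int, int, int] = (36, 140, 140)           # (z, y, x) voxels
    cell_semi_axes: tuple[float, float, float] = (4.5, 4.5, 3.0)  # (ax, ay, az) µm
    cell_center: tuple[float, float, float] | None = None        # (x, y, z) µm
    membrane_thickness: float = 0.24                             # µm
    membrane_intensity: float = 500.0
    psf_sigma: tuple[float, float, float] | None = (0.1, 0.1, 0.25)  # (sx, sy, sz) µm
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(a <= 0 for a in self.cell_semi_axes):
            raise ValueError("cell semi-axes must be positive")
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")
        if self.cell_center is None:
            dz, dy, dx = self.voxel_size_zyx
            nz, ny, nx = self.stack_shape
            self.cell_center = (nx * dx / 2, ny * dy / 2, nz * dz / 2)

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        dx, dy, dz = self.voxel_size
        return (dz, dy, dx)


@dataclass
class GroundTruthSpot:
    """One analytic punctum: an axis-aligned ellipsoid (sphere if equal axes)."""

    channel: str
    semi_axes: tuple[float, float, float]        # (x, y, z) µm
    center: tuple[float, float, float]           # (x, y, z) µm
    placement: str = "cytosol"                   # "membrane" | "cytosol"
    gap: float = 0.0                             # boundary-to-membrane gap, µm
    partner_id: int | None = None
    intensity: float = 1000.0
    spot_id: int | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("spot semi-axes must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def true_volume(self) -> float:
        return ellipsoid_volume(*self.semi_axes)

    @property
    def true_sphericity(self) -> float:
        return ellipsoid_sphericity(*self.semi_axes)


@dataclass
class GroundTruthTransient:
    """Stimulus-locked fluorescence transient at one hotspot.

    ``decay_tau`` (s) governs within-stimulus decay (``inf`` → flat plateau);
    ``clear_tau`` governs post-stimulus clearance.
    """

    roi_center: tuple[float, float]              # (x, y) µm
    f0: float = 100.0
    amplitude: float = 50.0
    onset_frame: int = 10
    duration_frames: int = 10
    decay_tau: float = math.inf
    clear_tau: float = 0.25
    radius_um: float = 0.8

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("F0 must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * math.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Thomsen approximation (max error ~1%)."""
    p = 1.6075
    return 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


def ellipsoid_sphericity(a: float, b: float, c: float) -> float:
    v = ellipsoid_volume(a, b, c)
    s = ellipsoid_surface_area(a, b, c)
    return math.pi ** (1 / 3) * (6 * v) ** (2 / 3) / s


# ---------------------------------------------------------------------------
# geometry helpers


def _grids_um(config: SimConfig):
    """Physical-coordinate grids (z, y, x) in µm at voxel centers."""
    dz, dy, dx = config.voxel_size_zyx
    nz, ny, nx = config.stack_shape
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def ellipsoid_signed_distance(config: SimConfig) -> np.ndarray:
    """Approximate signed Euclidean distance to the cell surface (µm).

    Negative inside.  First-order: d ≈ (F − 1)/|∇F| for the implicit
    ellipsoid function F; accurate near the surface, which is all the shell
    rendering needs.
    """
    cx, cy, cz = config.cell_center
    ax, ay, az = config.cell_semi_axes
    zg, yg, xg = _grids_um(config)
    u, v, w = (xg - cx) / ax, (yg - cy) / ay, (zg - cz) / az
    f = np.sqrt(u * u + v * v + w * w)
    f = np.maximum(f, 1e-9)
    grad = np.sqrt((u / ax) ** 2 + (v / ay) ** 2 + (w / az) ** 2) / f
    return (f - 1.0) / np.maximum(grad, 1e-9)


def _surface_point_and_normal(config: SimConfig, direction):
    """Point on the cell surface along ``direction`` from the center, and the
    outward unit normal there.  All vectors (x, y, z)."""
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    ax, ay, az = config.cell_semi_axes
    t = 1.0 / math.sqrt((d[0] / ax) ** 2 + (d[1] / ay) ** 2 + (d[2] / az) ** 2)
    p = np.asarray(config.cell_center) + t * d
    rel = p - np.asarray(config.cell_center)
    n = rel / np.array([ax**2, ay**2, az**2])
    n /= np.linalg.norm(n)
    return p, n


def _ellipsoid_radius_along(semi_axes, direction) -> float:
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    ax, ay, az = semi_axes
    return 1.0 / math.sqrt((d[0] / ax) ** 2 + (d[1] / ay) ** 2 + (d[2] / az) ** 2)


def place_membrane_spot(
    config: SimConfig,
    channel: str,
    direction,
    semi_axes,
    gap: float = 0.0,
    partner_id: int | None = None,
    intensity: float = 1000.0,
) -> GroundTruthSpot:
    """Anchor a punctum just under the membrane along a radial direction.

    The spot's boundary sits ``gap`` µm inside the inner face of the membrane
    shell (shell spans ± thickness/2 about the analytic surface).
    """
    if np.isscalar(semi_axes):
        semi_axes = (float(semi_axes),) * 3
    p, n = _surface_point_and_normal(config, direction)
    r_along = _ellipsoid_radius_along(semi_axes, n)
    depth = config.membrane_thickness / 2.0 + gap + r_along
    center = p - n * depth
    return GroundTruthSpot(
        channel=channel,
        semi_axes=tuple(semi_axes),
        center=tuple(center),
        placement="membrane",
        gap=gap,
        partner_id=partner_id,
        intensity=intensity,
    )


def place_cytosolic_spot(
    config: SimConfig,
    channel: str,
    center,
    semi_axes,
    intensity: float = 1000.0,
) -> GroundTruthSpot:
    if np.isscalar(semi_axes):
        semi_axes = (float(semi_axes),) * 3
    return GroundTruthSpot(
        channel=channel,
        semi_axes=tuple(semi_axes),
        center=tuple(center),
        placement="cytosol",
        intensity=intensity,
    )


def random_syribbon_spots(
    config: SimConfig,
    n_pairs: int = 12,
    rng: np.random.Generator | None = None,
    ribeye_channel: str = "RIBEYE",
    bassoon_channel: str = "Bassoon",
    cav_channel: str | None = None,
    pair_gap: float = 0.02,
    volume_range: tuple[float, float] = (0.02, 1.0),
    n_cytosolic: int = 0,
) -> list[GroundTruthSpot]:
    """Membrane-anchored punctum pairs (triples with a Ca_V channel).

    Radii are drawn so spot volumes are log-uniform over ``volume_range``
    (µm³), emulating the broad, right-skewed volume distributions of the
    reconstituted structures.  Pairs share a radial direction; the partner sits
    ``pair_gap`` µm deeper.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spots: list[GroundTruthSpot] = []
    # keep away from poles so the equatorial central planes see the spots
    for i in range(n_pairs):
        theta = rng.uniform(0, 2 * math.pi)
        zdir = rng.uniform(-0.35, 0.35)
        direction = (math.cos(theta), math.sin(theta), zdir)
        v1, v2 = np.exp(rng.uniform(np.log(volume_range[0]), np.log(volume_range[1]), 2))
        r1 = (3 * v1 / (4 * math.pi)) ** (1 / 3)
        r2 = (3 * v2 / (4 * math.pi)) ** (1 / 3)
        sid = len(spots)
        spots.append(
            place_membrane_spot(config, ribeye_channel, direction, r1, gap=0.0, partner_id=sid + 1)
        )
        spots.append(
            place_membrane_spot(
                config, bassoon_channel, direction, (r2, r2, 0.6 * r2),
                gap=2 * r1 + pair_gap, partner_id=sid,
            )
        )
        if cav_channel is not None:
            rc = 0.8 * r1
            spots.append(
                place_membrane_spot(config, cav_channel, direction, rc, gap=0.0, partner_id=sid)
            )
    for _ in range(n_cytosolic):
        frac = rng.uniform(0.0, 0.4, 3)
        center = np.asarray(config.cell_center) + frac * np.asarray(config.cell_semi_axes)
        v = np.exp(rng.uniform(np.log(0.5), np.log(2.5)))
        r = (3 * v / (4 * math.pi)) ** (1 / 3)
        spots.append(place_cytosolic_spot(config, ribeye_channel, tuple(center), r))
    return spots


# ---------------------------------------------------------------------------
# stack generator


def _render_spot(volume: np.ndarray, config: SimConfig, spot: GroundTruthSpot,
                 supersample: int = 3) -> None:
    """Add an antialiased ellipsoid to ``volume`` in place.

    Each voxel in the spot's bounding box is subdivided ``supersample`` times
    per axis; the voxel gets ``intensity × covered fraction``, so summed
    intensity matches the analytic volume to sub-percent accuracy.
    """
    dz, dy, dx = config.voxel_size_zyx
    sx, sy, sz = spot.semi_axes
    cx, cy, cz = spot.center
    lo = [int((cz - sz) / dz) - 1, int((cy - sy) / dy) - 1, int((cx - sx) / dx) - 1]
    hi = [int((cz + sz) / dz) + 2, int((cy + sy) / dy) + 2, int((cx + sx) / dx) + 2]
    lo = [max(0, v) for v in lo]
    hi = [min(n, v) for v, n in zip(hi, volume.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    s = supersample
    steps = {
        0: (np.arange(lo[0], hi[0])[:, None] + (np.arange(s) + 0.5) / s).ravel() * dz,
        1: (np.arange(lo[1], hi[1])[:, None] + (np.arange(s) + 0.5) / s).ravel() * dy,
        2: (np.arange(lo[2], hi[2])[:, None] + (np.arange(s) + 0.5) / s).ravel() * dx,
    }
    zz = ((steps[0] - cz) / sz) ** 2
    yy = ((steps[1] - cy) / sy) ** 2
    xx = ((steps[2] - cx) / sx) ** 2
    inside = (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]) <= 1.0
    nzb, nyb, nxb = hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2]
    frac = inside.reshape(nzb, s, nyb, s, nxb, s).mean(axis=(1, 3, 5))
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += spot.intensity * frac


def generate_cell_stack(
    config: SimConfig,
    spots: list[GroundTruthSpot],
    membrane_channel: str = "membrane",
) -> tuple[ImageStack, pd.DataFrame]:
    """Render the cell and its puncta into a multi-channel stack.

    Channel 0 is the membrane shell; each distinct spot channel follows in
    order of first appearance.  Returns the stack and a ground-truth table
    with one row per spot.
    """
    sdf = ellipsoid_signed_distance(config)
    half = config.membrane_thickness / 2.0
    channels = [membrane_channel]
    for s in spots:
        if s.channel not in channels:
            channels.append(s.channel)

    dz, dy, dx = config.voxel_size_zyx
    nz, ny, nx = config.stack_shape
    extent = (nx * dx, ny * dy, nz * dz)

    cx0, cy0, cz0 = config.cell_center
    ax, ay, az = config.cell_semi_axes
    rows = []
    data = np.zeros((len(channels),) + tuple(config.stack_shape), dtype=float)
    data[0][np.abs(sdf) <= half] = config.membrane_intensity

    for i, spot in enumerate(spots):
        spot.spot_id = i
        rel = (np.asarray(spot.center) - np.asarray((cx0, cy0, cz0))) / np.asarray((ax, ay, az))
        if spot.placement == "membrane" and np.linalg.norm(rel) > 1.0:
            raise ValueError(
                f"membrane spot {i} ({spot.channel}) lies outside the cell: "
                f"center {spot.center} vs semi-axes {config.cell_semi_axes}"
            )
        pad = max(spot.semi_axes)
        if config.psf_sigma:
            pad += 2 * max(config.psf_sigma)
        for c, e in zip(spot.center, extent):
            if c - pad < 0 or c + pad > e:
                raise ValueError(
                    f"spot {i} ({spot.channel}) does not fit inside the stack after blur padding"
                )
        _render_spot(data[channels.index(spot.channel)], config, spot)
        rows.append(
            {
                "spot_id": i,
                "channel": spot.channel,
                "center_x_um": spot.center[0],
                "center_y_um": spot.center[1],
                "center_z_um": spot.center[2],
                "semi_axis_x_um": spot.semi_axes[0],
                "semi_axis_y_um": spot.semi_axes[1],
                "semi_axis_z_um": spot.semi_axes[2],
                "true_volume_um3": spot.true_volume,
                "true_sphericity": spot.true_sphericity,
                "placement": spot.placement,
                "gap_um": spot.gap,
                "partner_id": spot.partner_id,
                "intensity": spot.intensity,
            }
        )

    if config.psf_sigma:
        sigma_vox = [s / v for s, v in zip(config.psf_sigma[::-1], config.voxel_size_zyx)]
        for c in range(data.shape[0]):
            data[c] = ndi.gaussian_filter(data[c], sigma_vox)

    rng = np.random.default_rng(config.seed)
    for c in range(data.shape[0]):
        data[c] = config.noise.apply(data[c], rng)

    stack = ImageStack(data, config.voxel_size_zyx, channels=channels)
    return stack, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-series generator


def _transient_timecourse(tr: GroundTruthTransient, n_frames: int, frame_rate: float) -> np.ndarray:
    """Unit response: exp-decaying plateau during the stimulus, exponential
    clearance afterwards.  decay_tau=inf gives a flat box."""
    t = np.arange(n_frames, dtype=float)
    u = np.zeros(n_frames)
    o, d = tr.onset_frame, tr.duration_frames
    stim = (t >= o) & (t < o + d)
    if math.isinf(tr.decay_tau):
        u[stim] = 1.0
        u_end = 1.0
    else:
        u[stim] = np.exp(-(t[stim] - o) / (tr.decay_tau * frame_rate))
        u_end = math.exp(-(d - 1) / (tr.decay_tau * frame_rate))
    post = t >= o + d
    if tr.clear_tau > 0 and math.isfinite(tr.clear_tau):
        u[post] = u_end * np.exp(-(t[post] - (o + d - 1)) / (tr.clear_tau * frame_rate))
    else:
        u[post] = u_end
    return u


def generate_timeseries(
    config: SimConfig,
    transients: list[GroundTruthTransient],
    n_frames: int = 60,
    frame_rate: float = 20.0,
    cell_f0: float = 80.0,
    diffuse_amplitude: float = 0.0,
    diffuse_transient: GroundTruthTransient | None = None,
) -> tuple[TimeSeries, pd.DataFrame]:
    """Simulate the single-plane indicator movie.

    The cell's equatorial cross-section carries baseline ``cell_f0``; each
    transient's hotspot disc carries its own ``F0`` plus the stimulus-locked
    response.  ``diffuse_amplitude`` adds the same response over the whole
    membrane ring to emulate non-clustered channels.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    for tr in transients:
        if n_frames <= tr.onset_frame + tr.duration_frames:
            raise ValueError("n_frames must exceed onset + duration for every transient")

    dz, dy, dx = config.voxel_size_zyx
    _, ny, nx = config.stack_shape
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx
    xg, yg = np.meshgrid(x, y)
    cx0, cy0, _ = config.cell_center
    ax, ay, _ = config.cell_semi_axes
    rho = np.sqrt(((xg - cx0) / ax) ** 2 + ((yg - cy0) / ay) ** 2)
    cell = rho <= 1.0
    ring = cell & (rho >= 1.0 - config.membrane_thickness / min(ax, ay))

    base = np.where(cell, cell_f0, 0.0)
    frames = np.repeat(base[None], n_frames, axis=0)

    rows = []
    for i, tr in enumerate(transients):
        disc = (xg - tr.roi_center[0]) ** 2 + (yg - tr.roi_center[1]) ** 2 <= tr.radius_um**2
        u = _transient_timecourse(tr, n_frames, frame_rate)
        frames[:, disc] = tr.f0 + tr.amplitude * u[:, None]
        rows.append(
            {
                "transient_id": i,
                "roi_x_um": tr.roi_center[0],
                "roi_y_um": tr.roi_center[1],
                "f0": tr.f0,
                "amplitude": tr.amplitude,
                "onset_frame": tr.onset_frame,
                "duration_frames": tr.duration_frames,
                "decay_tau_s": tr.decay_tau,
                "radius_um": tr.radius_um,
            }
        )

    if diffuse_amplitude > 0:
        ref = diffuse_transient or (transients[0] if transients else None)
        if ref is None:
            raise ValueError("diffuse component needs a reference transient for timing")
        u = _transient_timecourse(ref, n_frames, frame_rate)
        frames[:, ring] += diffuse_amplitude * u[:, None]

    if config.psf_sigma:
        sig = (config.psf_sigma[1] / dy, config.psf_sigma[0] / dx)
        for t in range(n_frames):
            frames[t] = ndi.gaussian_filter(frames[t], sig)

    rng = np.random.default_rng(config.seed)
    frames = config.noise.apply(frames, rng)
    return TimeSeries(frames, (dy, dx), frame_rate), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IV generator


DEFAULT_PROTOCOL = np.arange(-65.0, 80.0 + 1e-9, 5.0)  # command; −86.2…58.8 after LJP 21.2


def generate_iv_recording(
    vhalf: float = -15.0,
    slope_k: float = 8.0,
    g_max: float = 2.0,
    v_rev: float = 60.0,
    leak_conductance: float = 0.3,
    capacitance: float = 12.0,
    rs: float = 8.0,
    noise_sd: float = 0.0,
    protocol: np.ndarray | None = None,
    ljp: float = 21.2,
    holding_command: float = -70.0,
    step_ms: float = 20.0,
    pre_ms: float = 5.0,
    post_ms: float = 5.0,
    sample_rate: float = 50_000.0,
    include_leak_sweeps: bool = True,
    seed: int = 0,
) -> IVRecording:
    """Simulate a step-depolarization IV protocol.

    Currents follow ``I(V) = g_max(V−v_rev)/(1+exp(−(V−vhalf)/k))`` plus
    linear leak ``g_leak(V−V_hold)``, relative to holding; the channel is
    taken as closed at the (far negative) holding potential.  Voltages in the
    protocol are command values; analysis corrects them by ``ljp``.
    ``g_max``/``leak_conductance`` in nS, capacitance pF, rs MΩ, noise pA.
    """
    if slope_k == 0:
        raise ValueError("slope_k must be nonzero")
    volts = DEFAULT_PROTOCOL.copy() if protocol is None else np.asarray(protocol, dtype=float)
    if not np.all(np.diff(volts) > 0):
        raise ValueError("protocol voltages must be strictly increasing")
    rng = np.random.default_rng(seed)

    n_pre = int(round(pre_ms * 1e-3 * sample_rate))
    n_step = int(round(step_ms * 1e-3 * sample_rate))
    n_post = int(round(post_ms * 1e-3 * sample_rate))
    n = n_pre + n_step + n_post
    vh_true = holding_command - ljp

    def activation(v_true):
        return g_max * (v_true - v_rev) / (1.0 + np.exp(-(v_true - vhalf) / slope_k))

    sweeps = np.zeros((len(volts), n))
    leak_sweeps = np.zeros_like(sweeps) if include_leak_sweeps else None
    for i, v_cmd in enumerate(volts):
        v_true = v_cmd - ljp
        i_step = activation(v_true) + leak_conductance * (v_true - vh_true)
        sweeps[i, n_pre:n_pre + n_step] = i_step
        if include_leak_sweeps:
            leak_sweeps[i, n_pre:n_pre + n_step] = leak_conductance * (v_true - vh_true) / 10.0
    if noise_sd > 0:
        sweeps += rng.normal(0.0, noise_sd, size=sweeps.shape)
        if include_leak_sweeps:
            leak_sweeps += rng.normal(0.0, noise_sd / math.sqrt(10), size=leak_sweeps.shape)

    return IVRecording(
        voltages=volts,
        sweeps=sweeps,
        sample_rate=sample_rate,
        onset_sample=n_pre,
        capacitance_pf=capacitance,
        series_resistance_mohm=rs,
        leak_current_pa=leak_conductance * vh_true,
        ljp_mv=ljp,
        holding_mv=holding_command,
        leak_sweeps=leak_sweeps,
        ground_truth={
            "vhalf": vhalf,
            "slope_k": slope_k,
            "g_max": g_max,
            "v_rev": v_rev,
            "leak_conductance": leak_conductance,
            "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# serialization


def write_ground_truth(out_dir, table: pd.DataFrame, config: SimConfig, stem: str = "ground_truth"):
    """Write the ground-truth table as CSV with a JSON config sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{stem}.csv", index=False)
    cfg = asdict(config)
    (out / f"{stem}.json").write_text(json.dumps(cfg, indent=2, default=str))
    return out / f"{stem}.csv"
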