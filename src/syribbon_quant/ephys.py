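"""Whole-cell IV-relation extraction and quality control.

Sweeps are stored baseline-subtracted: currents are relative to the holding
level, so a purely ohmic (leak-only) cell nulls out exactly under p/10
subtraction.  Sign convention is physiological: inward Ca²⁺ current is
negative.

The activation fit uses the standard Boltzmann-gated ohmic form

    I(V) = g_max · (V − V_rev) / (1 + exp(−(V − V_half) / k))

with ``g_max`` in nS when V is in mV and I in pA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class IVRecording:
    """One whole-cell voltage-clamp recording.

    ``voltages`` are command potentials (mV, one per sweep, strictly
    increasing); ``sweeps`` holds the corresponding current traces in pA,
    shape ``(n_sweeps, n_samples)``, baseline-subtracted.  ``onset_sample``
    marks the start of the depolarizing step.  ``leak_sweeps`` are the
    averaged responses to the p/10 pulses (same shape as ``sweeps``).
    """

    voltages: np.ndarray               # command, mV
    sweeps: np.ndarray                 # pA, (n_sweeps, n_samples)
    sample_rate: float                 # Hz
    onset_sample: int
    capacitance_pf: float
    series_resistance_mohm: float
    leak_current_pa: float
    ljp_mv: float = 21.2
    holding_mv: float = -70.0
    offset_drift_mv: float = 0.0
    ljp_corrected: bool = False
    leak_sweeps: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if not np.all(np.diff(self.voltages) > 0):
            raise ValueError("sweep voltages must be strictly increasing")
        if len(self.voltages) != self.sweeps.shape[0]:
            raise ValueError("one voltage per sweep required")
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class IVCurve:
    """Windowed IV relation with optional Boltzmann activation fit."""

    voltages: np.ndarray               # LJP-corrected, mV
    currents: np.ndarray               # pA
    current_densities: np.ndarray      # pA/pF
    window_ms: tuple[float, float]
    v_half: float | None = None
    slope_k: float | None = None
    g_max: float | None = None
    v_rev: float | None = None
    fit_ok: bool = False
    fit_rmse: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mv": self.voltages,
                "current_pa": self.currents,
                "current_density_pa_pf": self.current_densities,
            }
        )


@dataclass
class QCVerdict:
    passed: bool
    reasons: list[str]


def correct_ljp(recording: IVRecording) -> IVRecording:
    """Subtract the liquid junction potential from all command voltages.

    Applied offline, once; a second call is a no-op guarded by the
    ``ljp_corrected`` flag.
    """
    if recording.ljp_corrected:
        return recording
    return replace(
        recording,
        voltages=recording.voltages - recording.ljp_mv,
        holding_mv=recording.holding_mv - recording.ljp_mv,
        ljp_corrected=True,
    )


def leak_correct_p10(test_sweeps: np.ndarray, leak_sweeps: np.ndarray | None) -> np.ndarray:
    """Subtract the scaled p/10 leak response from each test sweep.

    ``leak_sweeps`` are responses to 1/10-amplitude replicas of the test
    pulses; if a repetition axis ``(n_sweeps, n_reps, n_samples)`` is given,
    repetitions are averaged first.  Corrected = test − 10 × leak.
    """
    if leak_sweeps is None:
        raise ValueError("missing leak sweeps: p/10 correction requires the scaled pulses")
    test = np.atleast_2d(np.asarray(test_sweeps, dtype=float))
    leak = np.asarray(leak_sweeps, dtype=float)
    if leak.ndim == 3:
        leak = leak.mean(axis=1)
    leak = np.atleast_2d(leak)
    if leak.shape != test.shape:
        raise ValueError(f"leak sweeps shape {leak.shape} does not match test sweeps {test.shape}")
    return test - 10.0 * leak


def extract_iv(
    recording: IVRecording,
    window_ms: tuple[float, float] = (5.0, 10.0),
    leak_correct: bool = False,
) -> IVCurve:
    """Average each sweep over a window after step onset to form the IV curve.

    The window (default 5–10 ms after depolarization onset) skips the
    capacitive transient while staying clear of inactivation.  Densities are
    currents divided by membrane capacitance.
    """
    rec = correct_ljp(recording)
    sweeps = rec.sweeps
    if leak_correct:
        sweeps = leak_correct_p10(sweeps, rec.leak_sweeps)
    lo = rec.onset_sample + int(round(window_ms[0] * 1e-3 * rec.sample_rate))
    hi = rec.onset_sample + int(round(window_ms[1] * 1e-3 * rec.sample_rate))
    if not (0 <= lo < hi <= sweeps.shape[1]):
        raise ValueError(
            f"window {window_ms} ms lies outside the {sweeps.shape[1]}-sample sweep"
        )
    currents = sweeps[:, lo:hi].mean(axis=1)
    return IVCurve(
        voltages=rec.voltages.copy(),
        currents=currents,
        current_densities=currents / rec.capacitance_pf,
        window_ms=tuple(window_ms),
    )


def _boltzmann_iv(v, g_max, v_half, k, v_rev):
    return g_max * (v - v_rev) / (1.0 + np.exp(-(v - v_half) / k))


def fit_activation(iv: IVCurve) -> IVCurve:
    """Least-squares Boltzmann-ohmic fit of the IV relation.

    Returns a copy of ``iv`` with ``v_half``, ``slope_k``, ``g_max`` and
    ``v_rev`` populated; on non-convergence the copy is flagged
    (``fit_ok=False``) and carries no values.
    """
    v, i = iv.voltages, iv.currents
    if len(v) < 8:
        raise ValueError("need at least 8 IV points spanning activation to fit")
    out = replace(iv)
    if np.allclose(i, 0):
        out.fit_ok = False
        return out
    # heuristics: peak inward current locates the activated branch; the
    # reversal is where current re-crosses zero at depolarized potentials
    i_peak = np.argmin(i)
    v_rev0 = 60.0
    above = np.where((v > v[i_peak]) & (i >= 0))[0]
    if len(above):
        v_rev0 = float(v[above[0]])
    g0 = abs(i[i_peak] / (v[i_peak] - v_rev0)) or 1.0
    p0 = (g0, v[i_peak] - 10.0, 8.0, v_rev0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(_boltzmann_iv, v, i, p0=p0, maxfev=20000)
        resid = i - _boltzmann_iv(v, *popt)
        scale = max(np.ptp(i), 1e-9)
        if not np.all(np.isfinite(popt)) or np.sqrt(np.mean(resid**2)) > 0.5 * scale:
            out.fit_ok = False
            return out
        out.g_max, out.v_half, out.slope_k, out.v_rev = map(float, popt)
        out.fit_rmse = float(np.sqrt(np.mean(resid**2)))
        out.fit_ok = True
    except RuntimeError:
        out.fit_ok = False
    return out


# QC thresholds as printed in the exclusion rules; compared on magnitudes
# (inward currents are negative).
QC_LEAK_PA = 50.0
QC_RS_MOHM = 15.0
QC_DRIFT_MV = 5.0
QC_MIN_PEAK_PA = 49.0
QC_MAX_DENSITY_PA_PF = 60.0


def qc_filter(recording: IVRecording, iv: IVCurve | None = None) -> QCVerdict:
    """Apply the recording exclusion rules; strict inequalities throughout.

    A recording fails when leak exceeds 50 pA in magnitude, series resistance
    exceeds 15 MΩ, the offset potential drifted by more than 5 mV, the peak
    inward current is smaller than 49 pA in magnitude (no expressing channel),
    or the peak inward density exceeds 60 pA/pF (clamp quality suspect).
    """
    if iv is None:
        # amplitude rules apply to the leak-corrected current when p/10
        # sweeps are available, as in the analysis proper
        iv = extract_iv(recording, leak_correct=recording.leak_sweeps is not None)
    reasons = []
    if abs(recording.leak_current_pa) > QC_LEAK_PA:
        reasons.append("leak_current")
    if recording.series_resistance_mohm > QC_RS_MOHM:
        reasons.append("series_resistance")
    if abs(recording.offset_drift_mv) > QC_DRIFT_MV:
        reasons.append("offset_drift")
    peak = float(np.min(iv.currents))
    if abs(peak) < QC_MIN_PEAK_PA:
        reasons.append("small_current")
    peak_density = float(np.min(iv.current_densities))
    if abs(peak_density) > QC_MAX_DENSITY_PA_PF:
        reasons.append("high_density")
    return QCVerdict(passed=not reasons, reasons=reasons)


def vhalf_compare(vhalfs_a, vhalfs_b):
    """Two-sided unpaired t-test on V_half values of two groups."""
    t, p = stats.ttest_ind(vhalfs_a, vhalfs_b)
    return {"t": float(t), "p": float(p)}
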