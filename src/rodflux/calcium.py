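"""Fluo-4 fluorescence trace processing.

Fluorescence is normalized to F_MAX (ionomycin in 30 mM Ca2+). The effective
dye dissociation constant is solved per cell from a calibration point at a
known free calcium concentration (494 nM by default), and traces are
converted to [Ca2+] with the single-wavelength relation

    linear form (default):   [Ca2+] = Kd * (F - F0) / (F_MAX - F0)
    hyperbolic form:         [Ca2+] = Kd * (F - F0) / (F_MAX - F)

The linear form divides by the full calibration range and is affine in F;
the hyperbolic form is the textbook single-wavelength saturation relation.
Both are provided because the two differ only near saturation and published
analyses are not always explicit about which was used; the dye form is an
explicit argument everywhere.

On converted (or normalized) traces this module measures depolarization-
evoked response amplitudes, baseline drift slopes, the store-content metric
triplet, and the fluorescence drop produced by the CSC blocker MRS-1845,
plus the quality-control filter on the 40 mM KCl response.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .protocols import K_LEVELS_MM, PerfusionProtocol, Segment, Solution

__all__ = [
    "DyeForm",
    "FluoTrace",
    "Calibration",
    "ResponseMeasure",
    "StoreMetrics",
    "normalize",
    "solve_kd",
    "to_calcium",
    "calcium_to_f",
    "response_amplitude",
    "baseline_drift",
    "store_metrics",
    "mrs_block",
    "qc_filter",
]

QC_THRESHOLD = 0.1  # minimum dF/F_MAX at 40 mM KCl; exactly 0.1 is kept
CA_CAL_NM = 494.0
DEFAULT_SAMPLE_RATE_HZ = 0.5


class DyeForm(str, enum.Enum):
    LINEAR = "linear"
    HYPERBOLIC = "hyperbolic"


@dataclass
class FluoTrace:
    """ROI-averaged fluorescence time series with its perfusion protocol."""

    time: np.ndarray  # s
    f: np.ndarray  # arbitrary units
    protocol: PerfusionProtocol
    cell_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time.shape != self.f.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("fluorescence contains non-finite values")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= t < t1."""
        return (self.time >= t0) & (self.time < t1)


@dataclass
class Calibration:
    """Per-cell dye calibration state.

    F0 is measured in 0 Ca/EGTA + ionomycin, F_MAX in 30 mM Ca + ionomycin,
    F_cal at the calibrated concentration ``ca_cal`` (nM).
    """

    f0: float
    f_max: float
    f_cal: float | None = None
    ca_cal: float = CA_CAL_NM
    kd: float | None = None
    dye_form: DyeForm = DyeForm.LINEAR

    def __post_init__(self) -> None:
        if not self.f0 < self.f_max:
            raise ValueError("calibration requires F0 < F_MAX")
        if self.f_cal is not None and not (self.f0 <= self.f_cal <= self.f_max):
            raise ValueError("F_cal must lie between F0 and F_MAX")
        if self.kd is not None and self.kd <= 0:
            raise ValueError("Kd must be positive")


def normalize(f: np.ndarray, f_max: float) -> np.ndarray:
    """F/F_MAX normalization."""
    if f_max <= 0:
        raise ValueError("F_MAX must be positive")
    return np.asarray(f, dtype=float) / f_max


def solve_kd(cal: Calibration) -> float:
    """Effective dye Kd (nM) from the calibration point.

    linear form:     Kd = Ca_cal * (F_MAX - F0) / (F_cal - F0)
    hyperbolic form: Kd = Ca_cal * (F_MAX - F_cal) / (F_cal - F0)
    """
    if cal.f_cal is None:
        raise ValueError("calibration point F_cal is required to solve for Kd")
    if cal.f_cal <= cal.f0:
        raise ValueError("F_cal must exceed F0: the calibration point carries no information")
    if cal.dye_form is DyeForm.HYPERBOLIC and cal.f_cal >= cal.f_max:
        raise ValueError("hyperbolic form requires F_cal < F_MAX")
    if cal.dye_form is DyeForm.LINEAR:
        return cal.ca_cal * (cal.f_max - cal.f0) / (cal.f_cal - cal.f0)
    return cal.ca_cal * (cal.f_max - cal.f_cal) / (cal.f_cal - cal.f0)


def to_calcium(f: np.ndarray, cal: Calibration) -> np.ndarray:
    """Convert fluorescence to [Ca2+] (nM) under the calibration's dye form.

    Under the hyperbolic form, samples at or above F_MAX are saturated and
    returned as NaN (flagged, not raised).
    """
    if cal.kd is None:
        raise ValueError("calibration has no Kd; call solve_kd first")
    f = np.asarray(f, dtype=float)
    if cal.dye_form is DyeForm.LINEAR:
        return cal.kd * (f - cal.f0) / (cal.f_max - cal.f0)
    out = np.full_like(f, np.nan, dtype=float)
    ok = f < cal.f_max
    out[ok] = cal.kd * (f[ok] - cal.f0) / (cal.f_max - f[ok])
    return out


def calcium_to_f(ca_nm: np.ndarray, cal: Calibration) -> np.ndarray:
    """Inverse of :func:`to_calcium`: fluorescence produced by [Ca2+] (nM)."""
    if cal.kd is None:
        raise ValueError("calibration has no Kd")
    ca = np.asarray(ca_nm, dtype=float)
    if cal.dye_form is DyeForm.LINEAR:
        return cal.f0 + (cal.f_max - cal.f0) * ca / cal.kd
    return (cal.f0 * cal.kd + cal.f_max * ca) / (cal.kd + ca)


@dataclass(frozen=True)
class ResponseMeasure:
    """Depolarization-evoked response at one [K]o level, on the F/F_MAX scale."""

    k_level: int  # mM
    baseline: float  # pre-application F/F_MAX
    amplitude: float  # dF/F_MAX


def _k_segment(protocol: PerfusionProtocol, k_level: int) -> Segment:
    for sol, mm in K_LEVELS_MM.items():
        if mm == k_level:
            segs = protocol.find(sol)
            if not segs:
                raise ValueError(f"protocol contains no {k_level} mM KCl segment")
            return segs[0]
    raise ValueError(f"unknown [K]o level {k_level} mM")


def response_amplitude(
    trace: FluoTrace,
    norm: np.ndarray,
    k_level: int,
    baseline_window_s: float = 20.0,
    response_stat: str = "max",
) -> ResponseMeasure:
    """Net evoked increase dF/F_MAX at one [K]o level.

    Baseline is the mean of the normalized trace over ``baseline_window_s``
    before segment onset; the response is the chosen statistic over the
    segment ("max", the default, or "plateau" = mean of the last third)
    minus the baseline.
    """
    seg = _k_segment(trace.protocol, k_level)
    pre = trace.window(seg.onset - baseline_window_s, seg.onset)
    during = trace.window(seg.onset, seg.end)
    if not pre.any() or not during.any():
        raise ValueError(f"no samples around the {k_level} mM KCl segment")
    baseline = float(np.mean(norm[pre]))
    if response_stat == "max":
        peak = float(np.max(norm[during]))
    elif response_stat == "plateau":
        vals = norm[during]
        peak = float(np.mean(vals[-max(len(vals) // 3, 1):]))
    else:
        raise ValueError(f"unknown response statistic {response_stat!r}")
    return ResponseMeasure(k_level=k_level, baseline=baseline, amplitude=peak - baseline)


def baseline_drift(time: np.ndarray, norm: np.ndarray, window: tuple[float, float]) -> float:
    """Least-squares slope of F/F_MAX versus time over a pre-stimulus window (1/s)."""
    time = np.asarray(time, float)
    norm = np.asarray(norm, float)
    mask = (time >= window[0]) & (time < window[1])
    if mask.sum() < 4:
        raise ValueError(f"drift window {window} s holds {int(mask.sum())} samples; need >= 4")
    slope, _ = np.polyfit(time[mask], norm[mask], 1)
    return float(slope)


@dataclass(frozen=True)
class StoreMetrics:
    """Store-content metric triplet from the 25 mM K / 0 Ca-EGTA / ionomycin sequence.

    rel_increase : ([Ca]_rec - [Ca]_baseline) / [Ca]_baseline
        relative buildup over baseline at the end of recovery.
    rel_drop : ([Ca]_0CaEGTA - [Ca]_rec) / [Ca]_rec
        relative drop when influx is blocked; more negative = more complete.
    recovery_ratio : dCa_iono / ([Ca]_rec - [Ca]_0CaEGTA)
        ionomycin-released calcium relative to the preceding drop; a proxy
        for how much of the drop the stores can refund.
    """

    ca_baseline: float  # nM
    ca_rec: float  # nM
    ca_0ca_egta: float  # nM
    d_ca_iono: float  # nM
    rel_increase: float
    rel_drop: float
    recovery_ratio: float


def store_metrics(
    trace: FluoTrace,
    ca: np.ndarray,
    baseline_window_s: float = 20.0,
    recovery_window_s: float = 5.0,
) -> StoreMetrics:
    """Compute the store-content metrics from a converted [Ca2+] trace.

    Requires the protocol to contain a 25 mM KCl segment followed by
    0 Ca/EGTA and then ionomycin in 0 Ca, in that order.
    """
    proto = trace.protocol
    k25 = proto.require(Solution.K25)
    egta = proto.require(Solution.ZERO_CA_EGTA)
    iono = proto.require(Solution.IONO_0CA)
    if not (k25.end <= egta.onset <= iono.onset):
        raise ValueError("expected segment order: 25 mM KCl, 0 Ca/EGTA, ionomycin in 0 Ca")
    ca = np.asarray(ca, float)

    pre = trace.window(k25.onset - baseline_window_s, k25.onset)
    rec = trace.window(egta.onset - recovery_window_s, egta.onset)
    in_egta = trace.window(egta.onset, egta.end)
    in_iono = trace.window(iono.onset, iono.end)
    for mask, name in ((pre, "baseline"), (rec, "recovery"), (in_egta, "0 Ca/EGTA"), (in_iono, "ionomycin")):
        if not mask.any():
            raise ValueError(f"no samples in the {name} window")

    ca_baseline = float(np.mean(ca[pre]))
    ca_rec = float(np.mean(ca[rec]))
    ca_floor = float(np.min(ca[in_egta]))  # the drop's extreme
    d_ca_iono = float(np.max(ca[in_iono])) - ca_floor
    return StoreMetrics(
        ca_baseline=ca_baseline,
        ca_rec=ca_rec,
        ca_0ca_egta=ca_floor,
        d_ca_iono=d_ca_iono,
        rel_increase=(ca_rec - ca_baseline) / ca_baseline,
        rel_drop=(ca_floor - ca_rec) / ca_rec,
        recovery_ratio=d_ca_iono / (ca_rec - ca_floor),
    )


def mrs_block(
    trace: FluoTrace,
    norm: np.ndarray,
    pre_window_s: float = 20.0,
    drug_window_s: float = 10.0,
) -> tuple[float, float]:
    """Fluorescence change produced by MRS-1845, with the pre-drug baseline.

    Returns (drop, baseline) on the F/F_MAX scale: drop = mean over the last
    ``drug_window_s`` of the drug segment minus the mean over ``pre_window_s``
    before it (negative when the blocker lowers fluorescence). The baseline
    is returned for use as the covariate in the ANCOVA.
    """
    seg = trace.protocol.require(Solution.MRS1845)
    pre = trace.window(seg.onset - pre_window_s, seg.onset)
    late = trace.window(seg.end - drug_window_s, seg.end)
    if not pre.any() or not late.any():
        raise ValueError("no samples around the MRS-1845 segment")
    baseline = float(np.mean(norm[pre]))
    return float(np.mean(norm[late])) - baseline, baseline


def qc_filter(
    responses_40mm: dict[str, float],
    threshold: float = QC_THRESHOLD,
) -> tuple[list[str], list[dict]]:
    """Discard cells whose 40 mM KCl response is below threshold.

    A response exactly at the threshold is kept ("smaller than" is discarded).
    Returns (kept cell ids, audit log); each exclusion is logged with its value.
    """
    kept: list[str] = []
    audit: list[dict] = []
    for cell, amp in responses_40mm.items():
        if amp >= threshold:
            kept.append(cell)
        else:
            audit.append(
                {"cell": cell, "reason": "dF/F_MAX at 40 mM KCl below threshold", "value": amp, "threshold": threshold}
            )
    return kept, audit
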