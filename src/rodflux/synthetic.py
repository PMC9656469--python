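"""Synthetic-data generators for every pipeline input.

Four generators emulate the study's raw data so the whole analysis chain is
testable offline:

* voltage-ramp sweep sets from the two-component Boltzmann forward model
  plus a linear leak and white Gaussian noise;
* cell-attached records from independent two-state Markov channels, summed,
  noise-added and passed through a single-pole low-pass filter;
* Fluo-4 fluorescence traces from a protocol-driven first-order relaxation
  model of intracellular [Ca2+], pushed through the dye model;
* WT/MUT cohorts drawn from per-genotype parameter distributions, with the
  derived per-cell measurements the statistics layer consumes.

The fluorescence generator is deliberately phenomenological (targets and
relaxation rates, not mechanistic fluxes): the analyses only need a
controllable forward model whose amplitudes, slopes and ratios can be set.
All randomness flows from one seeded generator per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import signal

from .calcium import Calibration, DyeForm, FluoTrace, calcium_to_f
from .iv_ramp import SweepSet, boltzmann_iv
from .protocols import K_LEVELS_MM, PerfusionProtocol, Solution, kcl_series
from .single_channel import PatchRecord

__all__ = [
    "RampSimParams",
    "ChannelSimParams",
    "FluoSimParams",
    "CohortParams",
    "simulate_ramp_sweeps",
    "simulate_channel_record",
    "simulate_fluorescence_trace",
    "simulate_cohort",
    "WT_COHORT",
    "MUT_COHORT",
]


# ---------------------------------------------------------------------------
# voltage ramps
# ---------------------------------------------------------------------------


class RampSimParams(BaseModel):
    """Forward-model parameters for a whole-cell voltage-ramp experiment."""

    g_ca: float = Field(0.29, ge=0.0)  # nS
    v_ca: float = -28.17  # mV
    s_ca: float = Field(9.80, gt=0.0)  # mV
    g_cl: float = Field(0.0, ge=0.0)  # nS
    v_cl: float = -30.0  # mV
    s_cl: float = Field(8.0, gt=0.0)  # mV
    e_rev: float = 50.0  # mV
    e_cl: float = 0.0  # mV
    g_leak: float = Field(0.0, ge=0.0)  # nS
    e_leak: float = 0.0  # mV
    noise_sd: float = Field(0.0, ge=0.0)  # pA
    n_sweeps: int = Field(9, ge=1)
    ramp_start: float = -80.0  # mV
    ramp_end: float = 50.0  # mV
    ramp_duration: float = 240.0  # ms
    sample_rate: float = 5000.0  # Hz

    @model_validator(mode="after")
    def _check(self) -> "RampSimParams":
        if self.ramp_start >= self.ramp_end:
            raise ValueError("ramp_start must be below ramp_end")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        return self


def simulate_ramp_sweeps(params: RampSimParams, seed: int) -> SweepSet:
    """Noisy replicate ramp sweeps from the Boltzmann forward model plus leak."""
    rng = np.random.default_rng(seed)
    n = int(round(params.ramp_duration / 1000.0 * params.sample_rate))
    time = np.arange(n) / params.sample_rate
    voltage = np.linspace(params.ramp_start, params.ramp_end, n)
    clean = boltzmann_iv(
        voltage,
        params.g_ca,
        params.v_ca,
        params.s_ca,
        params.g_cl,
        params.v_cl,
        params.s_cl,
        e_rev=params.e_rev,
        e_cl=params.e_cl,
    ) + params.g_leak * (voltage - params.e_leak)
    noise = rng.normal(0.0, params.noise_sd, size=(params.n_sweeps, n)) if params.noise_sd > 0 else 0.0
    current = clean[None, :] + noise * np.ones((params.n_sweeps, n))
    return SweepSet(time=time, voltage=voltage, current=current)


# ---------------------------------------------------------------------------
# single-channel records
# ---------------------------------------------------------------------------


class ChannelSimParams(BaseModel):
    """Two-state Markov gating parameters for a cell-attached simulation."""

    gamma: float = Field(13.30, gt=0.0)  # pS
    v_rev: float = 10.0  # mV
    k_open: float = Field(15.0, gt=0.0)  # 1/s
    k_close: float = Field(15.0, gt=0.0)  # 1/s
    n_channels: int = Field(1, ge=1)
    v_rest: float = -40.0  # mV
    vp_list: list[float] = Field(default_factory=lambda: [-50.0, -30.0, -10.0])
    noise_sd: float = Field(0.05, ge=0.0)  # pA
    filter_cutoff: float = Field(200.0, gt=0.0)  # Hz
    sample_rate: float = Field(1000.0, gt=0.0)  # Hz
    duration: float = Field(6.0, gt=0.0)  # s

    @model_validator(mode="after")
    def _check(self) -> "ChannelSimParams":
        if self.duration * self.sample_rate < 1.9 * self.sample_rate:
            raise ValueError("record must contain at least one 1.9 s stretch")
        return self


def _two_state_gating(
    n_samples: int, n_channels: int, k_open: float, k_close: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Number of open channels per sample, from independent two-state chains.

    Exact discretization of the continuous-time chain: over a step dt,
    P(open | open) = p + (1-p) e^{-dt/tau} and P(open | closed) =
    p (1 - e^{-dt/tau}) with p = k_open/(k_open + k_close) and
    tau = 1/(k_open + k_close).
    """
    p = k_open / (k_open + k_close)
    decay = np.exp(-dt * (k_open + k_close))
    p_oo = p + (1.0 - p) * decay
    p_co = p * (1.0 - decay)
    open_now = rng.random(n_channels) < p  # start at stationarity
    n_open = np.empty(n_samples, dtype=np.int64)
    u = rng.random((n_samples, n_channels))
    for i in range(n_samples):
        thresh = np.where(open_now, p_oo, p_co)
        open_now = u[i] < thresh
        n_open[i] = open_now.sum()
    return n_open


def _single_pole_lowpass(x: np.ndarray, cutoff: float, sample_rate: float) -> np.ndarray:
    alpha = 1.0 - np.exp(-2.0 * np.pi * cutoff / sample_rate)
    return signal.lfilter([alpha], [1.0, -(1.0 - alpha)], x)


def simulate_channel_record(params: ChannelSimParams, seed: int) -> list[PatchRecord]:
    """One filtered cell-attached record per pipette voltage.

    The open-channel current at transmembrane voltage V_trans = V_rest - Vp
    is gamma*(V_trans - V_rev); inward current is negative. White noise is
    added before the single-pole low-pass (the recording chain filters the
    summed signal).
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.sample_rate))
    dt = 1.0 / params.sample_rate
    records = []
    for vp in params.vp_list:
        v_trans = params.v_rest - vp
        i_unit = params.gamma * 1e-3 * (v_trans - params.v_rev)  # pS*mV = fA -> pA
        n_open = _two_state_gating(n, params.n_channels, params.k_open, params.k_close, dt, rng)
        current = n_open * i_unit
        if params.noise_sd > 0:
            current = current + rng.normal(0.0, params.noise_sd, size=n)
        current = _single_pole_lowpass(current, params.filter_cutoff, params.sample_rate)
        records.append(
            PatchRecord(current=current, vp=vp, sample_rate=params.sample_rate, v_rest=params.v_rest)
        )
    return records


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------


DEFAULT_K_RESPONSE_NM = {10: 60.0, 16: 120.0, 25: 250.0, 40: 420.0}


class FluoSimParams(BaseModel):
    """Generative parameters for a protocol-driven fluorescence trace.

    The internal calcium model is a discrete-time first-order relaxation
    toward a protocol-dependent target. Store depletion couples into an
    upward baseline drift (the CSC influx surrogate) at
    drift_gain * (1 - store_content) nM/s, and into the 0 Ca/EGTA floor,
    ca_floor_min + Ca_baseline * store_content * egta_floor_share: full
    stores hold [Ca2+] up when influx is blocked, depleted stores let it
    collapse to low nanomolar values.
    """

    ca_baseline: float = Field(400.0, gt=0.0)  # nM
    store_content: float = Field(1.0, ge=0.0, le=1.0)  # fraction of full
    k_response: dict[int, float] = Field(default_factory=lambda: dict(DEFAULT_K_RESPONSE_NM))  # nM
    recovery_deficit: float = Field(0.3, ge=0.0, le=1.0)
    drift_gain: float = Field(0.5, ge=0.0)  # nM/s per unit store depletion
    caffeine_release_gain: float = Field(100.0, ge=0.0)  # nM per unit store content
    iono_release_gain: float = Field(600.0, ge=0.0)  # nM per unit store content
    extrusion_rate: float = Field(0.15, gt=0.0)  # 1/s
    kd_true: float = Field(990.0, gt=0.0)  # nM
    f0_true: float = Field(10.0, gt=0.0)  # a.u.
    fmax_true: float = Field(100.0, gt=0.0)  # a.u.
    dye_form: DyeForm = DyeForm.LINEAR
    noise_sd: float = Field(0.0, ge=0.0)  # fluorescence units
    mrs_block_fraction: float = Field(0.8, ge=0.0, le=1.0)
    egta_floor_share: float = Field(0.5, ge=0.0, le=1.0)
    ca_floor_min: float = Field(0.0, ge=0.0)  # nM
    mn_quench_ca_nm: float = 100.0  # fluorescence reference level in Mn2+
    sample_rate: float = Field(0.5, gt=0.0)  # Hz
    tail_s: float = Field(30.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "FluoSimParams":
        if self.f0_true >= self.fmax_true:
            raise ValueError("F0 must be below F_MAX")
        if any(v < 0 for v in self.k_response.values()):
            raise ValueError("K-response gains must be non-negative")
        return self


def simulate_fluorescence_trace(
    params: FluoSimParams, protocol: PerfusionProtocol, seed: int
) -> FluoTrace:
    """Integrate the calcium model over the protocol and emit fluorescence."""
    for seg in protocol.segments:
        if not isinstance(seg.solution, Solution):
            raise ValueError(f"unknown solution label {seg.solution!r}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate
    time = np.arange(0.0, protocol.end + params.tail_s + dt / 2, dt)
    n = time.size
    relax = 1.0 - np.exp(-params.extrusion_rate * dt)
    iono_fast = 1.0 - np.exp(-5.0 * params.extrusion_rate * dt)

    cal = Calibration(
        f0=params.f0_true,
        f_max=params.fmax_true,
        kd=params.kd_true,
        dye_form=params.dye_form,
    )
    mn_level = float(calcium_to_f(np.array([params.mn_quench_ca_nm]), cal)[0])

    ca = params.ca_baseline
    base = params.ca_baseline
    store = params.store_content
    seg_base = base  # baseline at the onset of the current K segment
    seg_peak = ca
    prev_sol = Solution.LOCKE

    ca_series = np.empty(n)
    f_clamp = np.full(n, np.nan)  # direct fluorescence clamps (Mn2+ quench, 30 mM Ca)

    for i, t in enumerate(time):
        sol = protocol.active(float(t))
        if sol is not prev_sol:
            # leaving a K segment: part of the evoked rise sticks as new baseline
            if prev_sol in K_LEVELS_MM:
                base = base + params.recovery_deficit * max(seg_peak - seg_base, 0.0)
            # ionomycin in 0 Ca empties the store completely
            if prev_sol is Solution.IONO_0CA:
                store = 0.0
            if sol in K_LEVELS_MM:
                seg_base = base
                seg_peak = ca
            prev_sol = sol

        drift_scale = 1.0
        rate = relax
        if sol in K_LEVELS_MM:
            target = seg_base + params.k_response.get(K_LEVELS_MM[sol], 0.0)
        elif sol is Solution.ZERO_CA_EGTA:
            target = params.ca_floor_min + params.ca_baseline * store * params.egta_floor_share
        elif sol is Solution.IONO_0CA:
            # transient release: the store empties during the segment while
            # released calcium is extruded / chelated toward the floor
            target = params.ca_floor_min + params.iono_release_gain * store
            store *= np.exp(-8.0 * dt / max(protocol.require(Solution.IONO_0CA).duration, dt))
            rate = iono_fast
        elif sol is Solution.IONO_30CA:
            # saturating calcium: the dye reads F_MAX
            ca_series[i] = params.kd_true if params.dye_form is DyeForm.LINEAR else 100.0 * params.kd_true
            ca = ca_series[i]
            f_clamp[i] = params.fmax_true
            continue
        elif sol is Solution.CA_494:
            ca = 494.0
            ca_series[i] = ca
            continue
        elif sol is Solution.CAFFEINE:
            target = base + params.caffeine_release_gain * store
        elif sol is Solution.MRS1845:
            drift_scale = 1.0 - params.mrs_block_fraction
            base += params.drift_gain * (1.0 - store) * dt * drift_scale
            # the CSC-maintained elevation above the resting level is blocked
            target = params.ca_baseline + (base - params.ca_baseline) * (1.0 - params.mrs_block_fraction)
        elif sol is Solution.MN_QUENCH:
            ca_series[i] = ca
            f_clamp[i] = mn_level
            continue
        else:  # LOCKE or THAPSIGARGIN: resting drift
            base += params.drift_gain * (1.0 - store) * dt
            target = base

        ca += (target - ca) * rate
        if sol in K_LEVELS_MM:
            seg_peak = max(seg_peak, ca)
        ca_series[i] = ca

    f = calcium_to_f(ca_series, cal)
    clamped = ~np.isnan(f_clamp)
    f[clamped] = f_clamp[clamped]
    if params.noise_sd > 0:
        f = f + rng.normal(0.0, params.noise_sd, size=n)
    return FluoTrace(time=time, f=f, protocol=protocol)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


#: Per-genotype (mean, sd) parameter distributions. Means follow the printed
#: group values where the study reports them (baseline [Ca2+], Kd, g_Ca,
#: conductance-density-implied C_m, drift magnitudes, caffeine responses);
#: dispersions are set to the printed SEM * sqrt(n) where available.
WT_COHORT: dict[str, tuple[float, float]] = {
    "ca_baseline": (477.65, 120.0),
    "store_content": (0.85, 0.08),
    "drift_gain": (0.60, 0.15),
    "recovery_deficit": (0.25, 0.08),
    "caffeine_release_gain": (100.0, 25.0),
    "iono_release_gain": (600.0, 100.0),
    "kd_true": (990.25, 140.0),
    "k_response_scale": (1.0, 0.2),
    "g_ca": (0.29, 0.134),
    "c_m": (20.0, 3.0),
}

MUT_COHORT: dict[str, tuple[float, float]] = {
    "ca_baseline": (260.43, 100.0),
    "store_content": (0.20, 0.08),
    "drift_gain": (0.60, 0.15),
    "recovery_deficit": (0.55, 0.10),
    "caffeine_release_gain": (100.0, 25.0),
    "iono_release_gain": (600.0, 100.0),
    "kd_true": (932.79, 200.0),
    "k_response_scale": (0.40, 0.10),
    "g_ca": (0.10, 0.11),
    "c_m": (15.1, 2.5),
}

_CLIP_RANGES = {
    "ca_baseline": (50.0, 2000.0),
    "store_content": (0.02, 1.0),
    "drift_gain": (0.0, 10.0),
    "recovery_deficit": (0.0, 1.0),
    "caffeine_release_gain": (0.0, 1e4),
    "iono_release_gain": (0.0, 1e5),
    "kd_true": (100.0, 1e4),
    "k_response_scale": (0.05, 10.0),
    "g_ca": (0.005, 10.0),
    "c_m": (1.0, 50.0),
}


class CohortParams(BaseModel):
    """Per-genotype parameter distributions and cohort sizes."""

    genotypes: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=lambda: {"WT": dict(WT_COHORT), "MUT": dict(MUT_COHORT)}
    )
    n_cells: dict[str, int] = Field(default_factory=lambda: {"WT": 34, "MUT": 37})
    k_levels: list[int] = Field(default_factory=lambda: [10, 16, 25, 40])
    noise_sd: float = Field(0.3, ge=0.0)  # fluorescence units
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        for g, n in self.n_cells.items():
            if n < 2:
                raise ValueError(f"cohort {g!r} needs n_cells >= 2, got {n}")
            if g not in self.genotypes:
                raise ValueError(f"no parameter distributions for genotype {g!r}")
        for g, dists in self.genotypes.items():
            for k, (mean, sd) in dists.items():
                if sd < 0:
                    raise ValueError(f"{g}.{k}: sd must be non-negative")
        return self


def _draw(dists: Mapping[str, tuple[float, float]], rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for key, (mean, sd) in dists.items():
        lo, hi = _CLIP_RANGES.get(key, (-np.inf, np.inf))
        out[key] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return out


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw per-cell parameters, simulate traces, measure per-cell quantities.

    Returns a tidy table, one row per cell: the drawn parameters, the
    KCl-evoked dF/F_MAX at each level, the pre-stimulus baseline slope
    (F/F_MAX per second) and the capacitance-normalized conductance density.
    """
    from .calcium import baseline_drift, normalize, response_amplitude

    rng = np.random.default_rng(params.seed)
    protocol = kcl_series(levels=params.k_levels, first_onset=60.0)
    rows = []
    for genotype, dists in params.genotypes.items():
        if genotype not in params.n_cells:
            continue
        for c in range(params.n_cells[genotype]):
            draw = _draw(dists, rng)
            scale = draw.pop("k_response_scale", 1.0)
            g_ca = draw.pop("g_ca", np.nan)
            c_m = draw.pop("c_m", np.nan)
            sim = FluoSimParams(
                **draw,
                k_response={k: v * scale for k, v in DEFAULT_K_RESPONSE_NM.items()},
                noise_sd=params.noise_sd,
            )
            trace = simulate_fluorescence_trace(sim, protocol, seed=int(rng.integers(2**31)))
            norm = normalize(trace.f, sim.fmax_true)
            row = {
                "cell": f"{genotype}_{c:03d}",
                "genotype": genotype,
                **{k: v for k, v in draw.items()},
                "g_ca": g_ca,
                "c_m": c_m,
                "density": 1000.0 * g_ca / c_m if c_m > 0 else np.nan,
            }
            first_onset = min(s.onset for s in protocol.segments)
            row["baseline_slope"] = baseline_drift(trace.time, norm, (0.0, first_onset))
            for lv in params.k_levels:
                meas = response_amplitude(trace, norm, lv)
                row[f"resp_{lv}"] = meas.amplitude
                row[f"baseline_{lv}"] = meas.baseline
            rows.append(row)
    return pd.DataFrame(rows)
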