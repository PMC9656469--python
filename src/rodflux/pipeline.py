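"""Orchestration: configuration, end-to-end synthetic runs, reproduction.

``run_end_to_end`` simulates WT and MUT cohorts (fluorescence, voltage ramps
and cell-attached records), pushes them through the analysis modules and the
statistics layer, and returns a ``ResultBundle`` with tidy tables, fit
summaries, genotype contrasts and an audit log of every exclusion and
non-converged fit. ``reproduce_targets`` recomputes the published summary
statistics from their printed (mean, SEM, n) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import calcium, iv_ramp, single_channel, synthetic
from .calcium import DyeForm
from .reported import REPORTED_PEAKS, REPORTED_TTESTS, ReportedTTest
from .stats import t_from_summary, t_test

__all__ = ["RunConfig", "ResultBundle", "run_end_to_end", "reproduce_targets"]


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end synthetic run."""

    seed: int = 0
    n_cells: dict[str, int] = Field(default_factory=lambda: {"WT": 34, "MUT": 37})
    n_ramp_cells: int = Field(8, ge=2)
    leak_window: tuple[float, float] = (-80.0, -70.0)
    bin_width: float = Field(0.02, ge=0.02, le=0.05)
    dye_form: DyeForm = DyeForm.LINEAR
    baseline_window_s: float = Field(20.0, gt=0.0)
    stats_method: str = "pooled"
    ss_type: int = 2
    ramp_noise_sd: float = Field(1.0, ge=0.0)
    channel_duration_s: float = Field(6.0, ge=1.9)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        lo, hi = self.leak_window
        if not lo < hi:
            raise ValueError(f"leak window must satisfy lower < upper, got {self.leak_window}")
        if self.stats_method not in ("pooled", "welch"):
            raise ValueError("stats_method must be 'pooled' or 'welch'")
        if self.ss_type not in (1, 2, 3):
            raise ValueError("ss_type must be 1, 2 or 3")
        return self


@dataclass
class ResultBundle:
    """Everything an end-to-end run produces, traceable to config + seed."""

    config: RunConfig
    cohort: pd.DataFrame
    ramp_fits: pd.DataFrame
    channel_estimates: dict[str, dict]
    contrasts: dict[str, dict]
    audit: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"End-to-end synthetic run (seed {self.config.seed})"]
        lines.append(f"  cohort cells after QC: {len(self.cohort)}")
        for name, c in self.contrasts.items():
            lines.append(f"  {name}: t = {c['t']:.3f}, df = {c['df']:g}, p = {c['p']:.4g}")
        for g, est in self.channel_estimates.items():
            lines.append(f"  {g} unitary: gamma = {est['gamma_pS']:.2f} pS, V_rev = {est['v_rev_mV']:.1f} mV")
        lines.append(f"  audit entries: {len(self.audit)}")
        return "\n".join(lines)


_RAMP_GENOTYPE_PARAMS = {
    "WT": {"g_ca": 0.29, "v_ca": -28.17, "s_ca": 9.80},
    "MUT": {"g_ca": 0.10, "v_ca": -10.52, "s_ca": 10.41},
}

_CHANNEL_GENOTYPE_PARAMS = {
    "WT": {"gamma": 5.04, "v_rev": -50.0, "v_rest": -60.0},
    "MUT": {"gamma": 13.30, "v_rev": 10.0, "v_rest": -40.0},
}


def _run_ramps(config: RunConfig, rng: np.random.Generator, audit: list[dict]) -> pd.DataFrame:
    rows = []
    for genotype, pars in _RAMP_GENOTYPE_PARAMS.items():
        for c in range(config.n_ramp_cells):
            sim = synthetic.RampSimParams(
                **pars,
                g_cl=0.05,
                g_leak=0.05,
                noise_sd=config.ramp_noise_sd,
                n_sweeps=9,
            )
            sweeps = synthetic.simulate_ramp_sweeps(sim, seed=int(rng.integers(2**31)))
            model = iv_ramp.RampIVModel.from_sweepset(sweeps, leak_window=config.leak_window)
            res = model.fit()
            if not res.converged:
                audit.append({"stage": "iv_ramp", "cell": f"{genotype}_{c}", "reason": res.message})
            rows.append(
                {"cell": f"{genotype}_ramp_{c:02d}", "genotype": genotype, "true_g_ca": pars["g_ca"], **res.params,
                 "converged": res.converged}
            )
    return pd.DataFrame(rows)


def _run_channels(config: RunConfig, rng: np.random.Generator, audit: list[dict]) -> dict[str, dict]:
    out = {}
    for genotype, pars in _CHANNEL_GENOTYPE_PARAMS.items():
        sim = synthetic.ChannelSimParams(
            **pars,
            k_open=6.0,
            k_close=18.0,
            n_channels=1,
            vp_list=[-80.0, -40.0, 0.0, 40.0],
            noise_sd=0.04,
            duration=config.channel_duration_s,
        )
        records = synthetic.simulate_channel_record(sim, seed=int(rng.integers(2**31)))
        points = []
        for rec in records:
            pt = single_channel.analyze_record(rec, bin_width=config.bin_width)
            if pt is None:
                audit.append(
                    {"stage": "single_channel", "cell": genotype, "reason": f"no openings resolved at Vp {rec.vp}"}
                )
            else:
                points.append(pt)
        if len(points) >= 2:
            est = single_channel.fit_unitary_iv(points).to_dict()
        else:
            est = {"gamma_pS": float("nan"), "v_rev_mV": float("nan"), "n_points": len(points)}
            audit.append({"stage": "single_channel", "cell": genotype, "reason": "fewer than 2 unitary points"})
        est["true_gamma_pS"] = pars["gamma"]
        est["true_v_rev_mV"] = pars["v_rev"]
        out[genotype] = est
    return out


def run_end_to_end(config: RunConfig) -> ResultBundle:
    """Simulate WT/MUT cohorts, analyze them, and test the genotype contrasts."""
    audit: list[dict] = []
    rng = np.random.default_rng(config.seed)

    cohort_params = synthetic.CohortParams(n_cells=config.n_cells, seed=int(rng.integers(2**31)))
    cohort = synthetic.simulate_cohort(cohort_params)

    kept, qc_audit = calcium.qc_filter(dict(zip(cohort["cell"], cohort["resp_40"])))
    for entry in qc_audit:
        audit.append({"stage": "qc_filter", **entry})
    cohort = cohort[cohort["cell"].isin(kept)].reset_index(drop=True)

    ramp_fits = _run_ramps(config, rng, audit)
    channel_estimates = _run_channels(config, rng, audit)

    wt = cohort[cohort["genotype"] == "WT"]
    mut = cohort[cohort["genotype"] == "MUT"]
    contrasts = {}
    for name, col in [
        ("resp_25", "resp_25"),
        ("resp_40", "resp_40"),
        ("baseline_slope", "baseline_slope"),
        ("density", "density"),
    ]:
        res = t_test(wt[col], mut[col], method=config.stats_method)
        contrasts[name] = {"t": res.t, "df": res.df, "p": res.p, "wt_mean": float(wt[col].mean()),
                           "mut_mean": float(mut[col].mean())}
    fit_wt = ramp_fits[ramp_fits["genotype"] == "WT"]["g_ca"]
    fit_mut = ramp_fits[ramp_fits["genotype"] == "MUT"]["g_ca"]
    res = t_test(fit_wt, fit_mut, method=config.stats_method)
    contrasts["g_ca"] = {"t": res.t, "df": res.df, "p": res.p, "wt_mean": float(fit_wt.mean()),
                         "mut_mean": float(fit_mut.mean())}

    return ResultBundle(
        config=config,
        cohort=cohort,
        ramp_fits=ramp_fits,
        channel_estimates=channel_estimates,
        contrasts=contrasts,
        audit=audit,
    )


def reproduce_targets(tests: Sequence[ReportedTTest] | None = None) -> pd.DataFrame:
    """Recompute every published summary statistic from its printed inputs.

    Pooled-variance two-tailed t statistics are rebuilt from the printed
    (mean, SEM, n) triplets; unitary amplitudes from the printed histogram
    peak positions. Each row reports the recomputed value, the printed value
    and their relative deviation (compared on magnitudes: the sign of a
    two-sample t depends only on group ordering).
    """
    if tests is None:
        tests = REPORTED_TTESTS
    if not tests:
        raise ValueError("no reported statistics to reproduce")
    rows = []
    for rt in tests:
        res = t_from_summary(rt.g1, rt.g2, method="pooled")
        rows.append(
            {
                "key": rt.key,
                "label": rt.label,
                "kind": "pooled_t",
                "recomputed": res.t,
                "printed": rt.t_printed,
                "rel_dev": abs(abs(res.t) - abs(rt.t_printed)) / abs(rt.t_printed),
                "df": res.df,
                "df_printed": rt.df_printed,
                "rounding_limited": rt.rounding_limited,
            }
        )
    for key, info in REPORTED_PEAKS.items():
        peaks = np.sort(np.asarray(info["peaks"], dtype=float))
        closed = int(np.argmin(np.abs(peaks)))  # closed level: nearest the baseline
        amp = single_channel.peak_difference(peaks, closed)
        rows.append(
            {
                "key": f"peak_diff_{key}",
                "label": f"unitary amplitude by peak differencing ({key})",
                "kind": "peak_difference",
                "recomputed": amp,
                "printed": info["unitary_pA"],
                "rel_dev": abs(abs(amp) - abs(info["unitary_pA"])) / abs(info["unitary_pA"]),
                "df": np.nan,
                "df_printed": np.nan,
                "rounding_limited": False,
            }
        )
    return pd.DataFrame(rows)
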