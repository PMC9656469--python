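"""Whole-cell ramp and step analysis.

Macroscopic currents recorded in response to slow voltage ramps are averaged
across sweeps, corrected for the linear (ohmic) leak estimated over a
hyperpolarized window, and fitted with a two-component activation model: a
Boltzmann-gated calcium conductance reversing at +50 mV plus a Boltzmann-gated
chloride conductance reversing at 0 mV,

    I(V) = g_Ca / (1 + exp(-(V - V_Ca)/S_Ca)) * (V - E_rev)
         + g_Cl / (1 + exp(-(V - V_Cl)/S_Cl)) * (V - E_Cl)

with conductances in nS, voltages in mV and currents in pA. ``RampIVModel``
wraps the nonlinear fit; ``step_iv`` estimates membrane resistance from
steady-state currents during long voltage steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "SweepSet",
    "LeakFit",
    "RampIVModel",
    "RampIVResults",
    "StepIVResult",
    "boltzmann_iv",
    "average_sweeps",
    "fit_leak",
    "subtract_leak",
    "conductance_density",
    "step_iv",
]

E_REV_CA_MV = 50.0
E_CL_MV = 0.0
DEFAULT_LEAK_WINDOW = (-80.0, -70.0)
_VTOL = 1e-9  # voltage comparisons at 1e-9 mV tolerance


def boltzmann_iv(
    v: np.ndarray,
    g_ca: float,
    v_ca: float,
    s_ca: float,
    g_cl: float,
    v_cl: float,
    s_cl: float,
    e_rev: float = E_REV_CA_MV,
    e_cl: float = E_CL_MV,
) -> np.ndarray:
    """Two-component Boltzmann-activation I/V forward model (pA)."""
    v = np.asarray(v, dtype=float)
    act_ca = expit((v - v_ca) / s_ca)
    act_cl = expit((v - v_cl) / s_cl)
    return g_ca * act_ca * (v - e_rev) + g_cl * act_cl * (v - e_cl)


@dataclass
class SweepSet:
    """Aligned command-voltage / current arrays for a ramp or step protocol.

    ``current`` is (n_sweeps, n_samples); ``voltage`` is shared across sweeps.
    """

    time: np.ndarray  # s
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA, 2-D
    cell_id: str = ""
    genotype: str = ""
    c_m: float | None = None  # pF

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.atleast_2d(np.asarray(self.current, dtype=float))
        if self.voltage.shape != self.time.shape:
            raise ValueError("time and voltage must have equal length")
        if self.current.shape[1] != self.voltage.size:
            raise ValueError("sweeps must have the same length as the voltage axis")

    @property
    def n_sweeps(self) -> int:
        return self.current.shape[0]


def average_sweeps(sweeps: SweepSet | np.ndarray) -> np.ndarray:
    """Pointwise mean current across sweep replicates."""
    cur = sweeps.current if isinstance(sweeps, SweepSet) else np.atleast_2d(np.asarray(sweeps, float))
    if cur.shape[0] < 1:
        raise ValueError("need at least one sweep")
    return cur.mean(axis=0)


@dataclass(frozen=True)
class LeakFit:
    """Ohmic leak line fitted over a hyperpolarized voltage window."""

    slope: float  # nS (pA/mV)
    intercept: float  # pA
    window: tuple[float, float] = DEFAULT_LEAK_WINDOW


def _window_mask(voltage: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"leak window must satisfy lower < upper, got {window}")
    return (voltage >= lo - _VTOL) & (voltage <= hi + _VTOL)


def fit_leak(
    voltage: np.ndarray,
    current: np.ndarray,
    window: tuple[float, float] = DEFAULT_LEAK_WINDOW,
) -> LeakFit:
    """Ordinary least-squares line through samples inside the voltage window (endpoints inclusive)."""
    voltage = np.asarray(voltage, float)
    current = np.asarray(current, float)
    mask = _window_mask(voltage, window)
    if mask.sum() < 2:
        raise ValueError(
            f"leak window {window} mV contains {int(mask.sum())} samples; recorded voltage "
            f"range is [{voltage.min():.2f}, {voltage.max():.2f}] mV"
        )
    slope, intercept = np.polyfit(voltage[mask], current[mask], 1)
    return LeakFit(slope=float(slope), intercept=float(intercept), window=tuple(window))


def subtract_leak(voltage: np.ndarray, current: np.ndarray, leak: LeakFit) -> np.ndarray:
    """Remove the ohmic component: I(V) - (slope*V + intercept)."""
    voltage = np.asarray(voltage, float)
    return np.asarray(current, float) - (leak.slope * voltage + leak.intercept)


def conductance_density(g_ca_ns: float, c_m_pf: float) -> float:
    """Maximal conductance normalized to membrane capacitance, pS/pF."""
    if c_m_pf <= 0:
        raise ValueError("membrane capacitance must be positive")
    return 1000.0 * g_ca_ns / c_m_pf


_PARAM_NAMES = ("g_ca", "v_ca", "s_ca", "g_cl", "v_cl", "s_cl")


class RampIVModel:
    """Two-component Boltzmann activation model for a leak-subtracted ramp.

    Parameters
    ----------
    voltage, current : arrays (mV, pA)
        Leak-subtracted averaged ramp trace.
    e_rev, e_cl : float
        Fixed reversal potentials of the calcium and chloride components;
        never altered by fitting.
    """

    def __init__(
        self,
        voltage: np.ndarray,
        current: np.ndarray,
        e_rev: float = E_REV_CA_MV,
        e_cl: float = E_CL_MV,
    ) -> None:
        self.voltage = np.asarray(voltage, dtype=float)
        self.current = np.asarray(current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current must have equal length")
        self.e_rev = float(e_rev)
        self.e_cl = float(e_cl)

    @classmethod
    def from_sweepset(
        cls,
        sweeps: SweepSet,
        leak_window: tuple[float, float] = DEFAULT_LEAK_WINDOW,
        e_rev: float = E_REV_CA_MV,
        e_cl: float = E_CL_MV,
    ) -> "RampIVModel":
        """Average sweeps, fit and subtract the leak line, build the model."""
        mean = average_sweeps(sweeps)
        leak = fit_leak(sweeps.voltage, mean, leak_window)
        model = cls(sweeps.voltage, subtract_leak(sweeps.voltage, mean, leak), e_rev, e_cl)
        model.leak = leak
        return model

    # -- initialization heuristic -------------------------------------------------
    def _initial_guess(self) -> np.ndarray:
        v, i = self.voltage, self.current
        # half-activation from the voltage of steepest current change
        di = np.gradient(i, v)
        interior = (v > -60.0) & (v < 20.0)
        v0 = float(v[interior][np.argmax(np.abs(di[interior]))]) if interior.any() else -25.0
        return np.array([v0, 10.0, v0 - 5.0, 10.0])

    def _design(self, theta: np.ndarray) -> np.ndarray:
        v_ca, s_ca, v_cl, s_cl = theta
        v = self.voltage
        act_ca = expit((v - v_ca) / s_ca)
        act_cl = expit((v - v_cl) / s_cl)
        return np.column_stack([act_ca * (v - self.e_rev), act_cl * (v - self.e_cl)])

    def _profiled_conductances(self, theta: np.ndarray) -> np.ndarray:
        """Best non-negative (g_Ca, g_Cl) for fixed gating parameters."""
        g, _ = optimize.nnls(self._design(theta), self.current)
        return g

    def fit(
        self,
        init: Sequence[float] | None = None,
        bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    ) -> "RampIVResults":
        """Least-squares fit with unit weights; conductances bounded at 0.

        The model is partially linear: for fixed gating parameters
        (V_Ca, S_Ca, V_Cl, S_Cl) the conductances solve a non-negative
        linear least-squares problem. The fit therefore profiles the
        conductances out (variable projection) and searches only the
        four-dimensional gating space from several starting points, which
        avoids the local minima of a naive six-parameter descent. A final
        full six-parameter polish supplies the covariance matrix.

        Bounds keep the slopes in (0.1, 50) mV and half-activations in
        (-80, +40) mV, preventing the calcium and chloride branches from
        swapping (their labels are anchored by the fixed reversal potentials).
        """
        if bounds is None:
            bounds = ([0.0, -80.0, 0.1, 0.0, -80.0, 0.1], [np.inf, 40.0, 50.0, np.inf, 40.0, 50.0])
        lo = np.asarray(bounds[0], float)
        hi = np.asarray(bounds[1], float)
        theta_lo = lo[[1, 2, 4, 5]]
        theta_hi = hi[[1, 2, 4, 5]]

        def resid(theta: np.ndarray) -> np.ndarray:
            return self._design(theta) @ self._profiled_conductances(theta) - self.current

        if init is not None:
            starts = [np.asarray(init, float)[[1, 2, 4, 5]]]
        else:
            h = self._initial_guess()
            starts = [
                h,
                np.array([-28.0, 10.0, -30.0, 8.0]),
                np.array([-10.0, 10.0, -40.0, 10.0]),
                np.array([h[0], 5.0, h[0] + 10.0, 15.0]),
            ]
        best = None
        for s in starts:
            s = np.clip(s, theta_lo + 1e-6, theta_hi - 1e-6)
            sol = optimize.least_squares(resid, s, bounds=(theta_lo, theta_hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
        g = self._profiled_conductances(best.x)
        p0 = np.array([g[0], best.x[0], best.x[1], g[1], best.x[2], best.x[3]])
        p0 = np.clip(p0, lo + 1e-12, np.minimum(hi, 1e12))

        def model(v, *p):
            return boltzmann_iv(v, *p, e_rev=self.e_rev, e_cl=self.e_cl)

        converged = True
        message = "converged"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model,
                    self.voltage,
                    self.current,
                    p0=p0,
                    bounds=bounds,
                    method="trf",
                    maxfev=20000,
                    x_scale=[0.1, 10.0, 5.0, 0.1, 10.0, 5.0],
                )
        except RuntimeError as err:  # polish failed: keep the profiled solution, no covariance
            converged = best.success
            message = f"covariance polish failed: {err}"
            popt = p0
            pcov = np.full((6, 6), np.nan)
        resid_final = self.current - model(self.voltage, *popt)
        rss = float(resid_final @ resid_final)
        return RampIVResults(
            model=self,
            params=dict(zip(_PARAM_NAMES, map(float, popt))),
            cov=np.asarray(pcov, float),
            rss=rss,
            converged=converged,
            message=message,
        )


@dataclass
class RampIVResults:
    """Fitted two-component activation parameters with uncertainties."""

    model: RampIVModel
    params: dict[str, float]
    cov: np.ndarray
    rss: float
    converged: bool
    message: str = ""

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors from the fit covariance."""
        diag = np.diag(self.cov)
        return {k: float(np.sqrt(d)) if d >= 0 else float("nan") for k, d in zip(_PARAM_NAMES, diag)}

    def predict(self, voltage: np.ndarray | None = None) -> np.ndarray:
        v = self.model.voltage if voltage is None else np.asarray(voltage, float)
        return boltzmann_iv(
            v, *(self.params[k] for k in _PARAM_NAMES), e_rev=self.model.e_rev, e_cl=self.model.e_cl
        )

    def to_dict(self) -> dict:
        se = self.bse
        out = {f"{k}_nS" if k.startswith("g") else f"{k}_mV": v for k, v in self.params.items()}
        out.update({f"se_{k}": se[k] for k in _PARAM_NAMES})
        out.update(
            {
                "e_rev_mV": self.model.e_rev,
                "e_cl_mV": self.model.e_cl,
                "rss": self.rss,
                "converged": self.converged,
            }
        )
        return out

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Two-component Boltzmann I/V fit",
            f"  fixed reversals: E_rev = {self.model.e_rev:+.1f} mV, E_Cl = {self.model.e_cl:+.1f} mV",
            f"  converged: {self.converged}   RSS = {self.rss:.4g} pA^2",
            f"  {'param':<6} {'value':>12} {'SE':>12}",
        ]
        units = {"g_ca": "nS", "v_ca": "mV", "s_ca": "mV", "g_cl": "nS", "v_cl": "mV", "s_cl": "mV"}
        for k in _PARAM_NAMES:
            lines.append(f"  {k:<6} {self.params[k]:>12.4f} {se[k]:>12.4f}  {units[k]}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.voltage, self.model.current, lw=0.8, label="leak-subtracted data")
        ax.plot(self.model.voltage, self.predict(), lw=1.5, label="fit")
        ax.set_xlabel("voltage (mV)")
        ax.set_ylabel("current (pA)")
        ax.legend()
        return ax


@dataclass
class StepIVResult:
    """Steady-state step I/V and the membrane resistance over a voltage window."""

    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA, steady-state means
    sems: np.ndarray  # pA
    r_m: float  # GOhm (inf if the I/V is flat)
    r_m_se: float
    window: tuple[float, float]
    finite: bool = True


def step_iv(
    traces: Mapping[float, np.ndarray],
    sample_rate: float,
    step_duration_s: float = 2.0,
    average_window_s: float = 0.2,
    rm_window: tuple[float, float] = (-120.0, -90.0),
) -> StepIVResult:
    """Steady-state currents from long voltage steps and the membrane resistance.

    ``traces`` maps each step voltage (mV) to a (n_sweeps, n_samples) current
    array. The steady current is the mean over the last ``average_window_s``
    of the step; R_m is the inverse slope of the least-squares I/V line over
    ``rm_window``, in GOhm.
    """
    if average_window_s > step_duration_s:
        raise ValueError("averaging window exceeds the step duration")
    n_avg = max(int(round(average_window_s * sample_rate)), 1)
    volts, steady, sems = [], [], []
    for v, cur in sorted(traces.items()):
        cur = np.atleast_2d(np.asarray(cur, float))
        tail = cur[:, -n_avg:]
        per_sweep = tail.mean(axis=1)
        volts.append(float(v))
        steady.append(float(per_sweep.mean()))
        sems.append(float(per_sweep.std(ddof=1) / np.sqrt(len(per_sweep))) if len(per_sweep) > 1 else 0.0)
    volts_arr = np.array(volts)
    steady_arr = np.array(steady)
    mask = (volts_arr >= rm_window[0] - _VTOL) & (volts_arr <= rm_window[1] + _VTOL)
    if mask.sum() < 2:
        raise ValueError(f"need >=2 step voltages inside the R_m window {rm_window} mV")
    x, y = volts_arr[mask], steady_arr[mask]
    slope, intercept, _, _, slope_se = stats.linregress(x, y)
    if abs(slope) < 1e-12:  # flat I/V: infinite resistance, flagged
        return StepIVResult(volts_arr, steady_arr, np.array(sems), float("inf"), float("nan"), tuple(rm_window), finite=False)
    r_m = 1.0 / slope  # pA/mV = nS -> 1/nS = GOhm
    r_m_se = slope_se / slope**2  # delta method
    return StepIVResult(volts_arr, steady_arr, np.array(sems), float(r_m), float(r_m_se), tuple(rm_window))
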