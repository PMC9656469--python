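"""Cell-attached single-channel analysis.

Current records acquired at fixed pipette voltages are cut into 1.9 s
stretches, binned into all-points amplitude histograms (bin width 0.02 to
0.05 pA), and fitted with a sum of up to three Gaussian components

    C(x) = sum_i  A_i / (w_i * sqrt(pi/2)) * exp(-2 (x - xc_i)^2 / w_i^2)

where A_i is the area under component i, xc_i its peak position and w_i its
spread. The difference between adjacent peak positions gives the unitary
current amplitude; amplitudes at several transmembrane voltages
(V_trans = V_rest - Vp in the cell-attached configuration) are regressed
against voltage to estimate the unitary conductance (slope) and reversal
potential (x-intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PatchRecord",
    "AmplitudeHistogram",
    "AmplitudeMixtureModel",
    "MixtureResults",
    "UnitaryPoint",
    "UnitaryIVModel",
    "UnitaryIVResults",
    "gaussian_mixture_counts",
    "bin_amplitudes",
    "fit_mixture",
    "peak_difference",
    "unitary_amplitude",
    "transmembrane_voltage",
    "fit_unitary_iv",
]

STRETCH_DURATION_S = 1.9
BIN_WIDTH_RANGE_PA = (0.02, 0.05)


def transmembrane_voltage(vp: float, v_rest: float) -> float:
    """Transmembrane potential across a cell-attached patch: V_rest - Vp (mV)."""
    return v_rest - vp


@dataclass
class PatchRecord:
    """Cell-attached current record at one pipette voltage.

    Sign convention: inward current through the patch is negative.
    """

    current: np.ndarray  # pA
    vp: float  # pipette voltage, mV
    sample_rate: float = 1000.0  # Hz
    v_rest: float = -60.0  # assumed resting potential, mV

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)

    @property
    def v_trans(self) -> float:
        return transmembrane_voltage(self.vp, self.v_rest)

    def stretches(self, duration_s: float = STRETCH_DURATION_S) -> list[np.ndarray]:
        """Consecutive non-overlapping stretches of the stated duration."""
        n = int(round(duration_s * self.sample_rate))
        if n < 1 or n > self.current.size:
            raise ValueError(
                f"record of {self.current.size} samples cannot supply a "
                f"{duration_s} s stretch at {self.sample_rate} Hz"
            )
        return [self.current[i : i + n] for i in range(0, self.current.size - n + 1, n)]


@dataclass
class AmplitudeHistogram:
    """All-points amplitude histogram of one stretch."""

    edges: np.ndarray  # pA, uniform
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def bin_amplitudes(
    stretch: np.ndarray,
    bin_width: float = 0.02,
    strict: bool = True,
) -> AmplitudeHistogram:
    """Histogram a stretch at uniform bin width (0.02-0.05 pA).

    Total counts equal the number of samples. Outside the admissible width
    range a warning is issued; with ``strict=True`` this is an error instead.
    """
    lo, hi = BIN_WIDTH_RANGE_PA
    if not lo <= bin_width <= hi:
        msg = f"bin width {bin_width} pA outside the admissible range [{lo}, {hi}] pA"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    x = np.asarray(stretch, dtype=float)
    if x.size == 0:
        raise ValueError("empty stretch")
    span = x.max() - x.min()
    n_bins = max(int(np.ceil(span / bin_width)), 1)
    # pad the last edge so the maximum falls inside the final bin
    edges = x.min() + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= x.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(x, bins=edges)
    return AmplitudeHistogram(edges=edges, counts=counts)


def gaussian_mixture_counts(
    x: np.ndarray,
    areas: Sequence[float],
    widths: Sequence[float],
    centers: Sequence[float],
) -> np.ndarray:
    """Sum of area-parameterized Gaussians: A/(w*sqrt(pi/2)) * exp(-2(x-xc)^2/w^2)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for a, w, xc in zip(areas, widths, centers):
        out += a / (w * np.sqrt(np.pi / 2.0)) * np.exp(-2.0 * (x - xc) ** 2 / w**2)
    return out


@dataclass
class MixtureComponent:
    area: float  # counts * pA
    width: float  # pA
    center: float  # pA


def _merge_coincident(comps: list["MixtureComponent"], tol: float) -> list["MixtureComponent"]:
    """Merge components whose centers coincide within ``tol``.

    Distinct mixture peaks must correspond to distinct current levels; a
    least-squares fit of a non-Gaussian peak (filter smearing broadens the
    level distributions) sometimes splits one level into two components at
    the same center. Such pairs are pooled (area-weighted center, summed
    area, wider width) before peak differencing.
    """
    merged: list[MixtureComponent] = []
    for c in comps:  # comps sorted by center
        if merged and abs(c.center - merged[-1].center) < tol:
            prev = merged[-1]
            total = prev.area + c.area
            merged[-1] = MixtureComponent(
                area=total,
                width=max(prev.width, c.width),
                center=(prev.area * prev.center + c.area * c.center) / total,
            )
        else:
            merged.append(c)
    return merged


@dataclass
class MixtureResults:
    """Selected Gaussian-mixture fit to an amplitude histogram.

    ``components`` are sorted by center. ``candidates`` maps each attempted
    component count to its (rss, score) pair; non-converging candidate counts
    are recorded in ``excluded``.
    """

    histogram: AmplitudeHistogram
    components: list[MixtureComponent]
    rss: float
    candidates: dict[int, dict[str, float]]
    excluded: dict[int, str] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components])

    def predict(self, x: np.ndarray | None = None) -> np.ndarray:
        xx = self.histogram.centers if x is None else np.asarray(x, float)
        return gaussian_mixture_counts(
            xx,
            [c.area for c in self.components],
            [c.width for c in self.components],
            [c.center for c in self.components],
        )

    def summary(self) -> str:
        lines = [
            f"Amplitude-histogram mixture fit: N = {self.n_components}  RSS = {self.rss:.4g}",
            f"  {'component':<10}{'center (pA)':>13}{'width (pA)':>12}{'area':>12}",
        ]
        for i, c in enumerate(self.components, 1):
            lines.append(f"  {i:<10}{c.center:>13.3f}{c.width:>12.3f}{c.area:>12.3f}")
        lines.append("  candidate scores: " + ", ".join(f"N={n}: {d['score']:.1f}" for n, d in sorted(self.candidates.items())))
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.histogram
        ax.bar(h.centers, h.counts, width=h.bin_width, alpha=0.5, label="counts/bin")
        xx = np.linspace(h.edges[0], h.edges[-1], 400)
        ax.plot(xx, self.predict(xx), "r-", label=f"N={self.n_components} fit")
        ax.set_xlabel("current (pA)")
        ax.set_ylabel("counts")
        ax.legend()
        return ax


class AmplitudeMixtureModel:
    """Least-squares Gaussian-mixture model of an amplitude histogram.

    Components are counted from 1 up to ``max_components`` (<= 3); the
    retained count minimizes a BIC-style score n_bins*ln(RSS/n_bins) +
    penalty*3N*ln(n_bins), i.e. the smallest N is kept unless adding three
    parameters buys a sufficient RSS drop. The penalty multiplier is
    configurable and every candidate's score is reported.
    """

    def __init__(
        self,
        histogram: AmplitudeHistogram,
        max_components: int = 3,
        penalty: float = 1.0,
    ) -> None:
        if max_components < 1 or max_components > 3:
            raise ValueError("component count is limited to 1..3")
        if np.count_nonzero(histogram.counts) < 5:
            raise ValueError("need at least 5 occupied bins to fit a mixture")
        if histogram.counts.sum() == 0:
            raise ValueError("empty histogram")
        self.histogram = histogram
        self.max_components = max_components
        self.penalty = penalty

    # -- initialization: peaks of a lightly smoothed histogram ---------------------
    def _initial_guess(self, n: int) -> np.ndarray:
        h = self.histogram
        counts = h.counts.astype(float)
        kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
        # local maxima, strongest first
        interior = np.arange(1, len(smooth) - 1)
        is_peak = (smooth[interior] >= smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
        peak_idx = interior[is_peak]
        peak_idx = peak_idx[np.argsort(smooth[peak_idx])[::-1]]
        centers = list(h.centers[peak_idx[:n]])
        if len(centers) < n:  # fall back to quantile spread
            qs = np.linspace(0.2, 0.8, n)
            cum = np.cumsum(counts) / counts.sum()
            centers += [float(h.centers[np.searchsorted(cum, q)]) for q in qs[len(centers) :]]
        centers = sorted(centers)
        width0 = 2.0 * h.bin_width
        mass = counts.sum() * h.bin_width / n
        p0 = []
        for c in centers:
            p0 += [mass, width0, c]
        return np.array(p0)

    def _fit_n(self, n: int) -> tuple[np.ndarray, float]:
        h = self.histogram
        x, y = h.centers, h.counts.astype(float)

        def model(xx, *p):
            return gaussian_mixture_counts(xx, p[0::3], p[1::3], p[2::3])

        p0 = self._initial_guess(n)
        lo = [0.0, h.bin_width / 4.0, h.edges[0]] * n
        hi = [np.inf, (h.edges[-1] - h.edges[0]), h.edges[-1]] * n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, x, y, p0=p0, bounds=(lo, hi), method="trf", maxfev=20000
            )
        resid = y - model(x, *popt)
        return popt, float(resid @ resid)

    def fit(self) -> MixtureResults:
        h = self.histogram
        m = len(h.centers)
        candidates: dict[int, dict[str, float]] = {}
        excluded: dict[int, str] = {}
        fits: dict[int, np.ndarray] = {}
        for n in range(1, self.max_components + 1):
            if 3 * n >= m:
                excluded[n] = f"{m} bins cannot constrain {3 * n} parameters"
                continue
            try:
                popt, rss = self._fit_n(n)
            except RuntimeError as err:
                excluded[n] = str(err)
                continue
            score = m * np.log(max(rss, 1e-12) / m) + self.penalty * 3 * n * np.log(m)
            candidates[n] = {"rss": rss, "score": float(score)}
            fits[n] = popt
        if not candidates:
            raise RuntimeError(f"no mixture size converged: {excluded}")
        best = min(candidates, key=lambda n: candidates[n]["score"])
        popt = fits[best]
        comps = sorted(
            (
                MixtureComponent(area=float(a), width=float(w), center=float(c))
                for a, w, c in zip(popt[0::3], popt[1::3], popt[2::3])
            ),
            key=lambda c: c.center,
        )
        comps = _merge_coincident(comps, tol=3.0 * h.bin_width)
        return MixtureResults(
            histogram=h,
            components=comps,
            rss=candidates[best]["rss"],
            candidates=candidates,
            excluded=excluded,
        )


def fit_mixture(
    hist: AmplitudeHistogram, max_n: int = 3, penalty: float = 1.0
) -> MixtureResults:
    """Fit the amplitude histogram with 1..max_n Gaussian components."""
    return AmplitudeMixtureModel(hist, max_components=max_n, penalty=penalty).fit()


def peak_difference(centers: Sequence[float], closed_index: int) -> float:
    """Mean adjacent spacing of peak positions, signed from the closed level.

    ``centers`` are sorted internally; ``closed_index`` locates the closed
    level within the sorted ladder. Openings walk away from the closed peak:
    if the closed level sits at the top of the ladder the openings are
    downward (inward current, negative amplitude).
    """
    c = np.sort(np.asarray(centers, dtype=float))
    if c.size < 2:
        raise ValueError("need at least two peaks")
    step = float(np.diff(c).mean())
    sign = -1.0 if closed_index >= c.size - 1 else 1.0
    return sign * step


def unitary_amplitude(fit: MixtureResults) -> float | None:
    """Unitary current from the spacing of mixture peaks (pA), or None.

    One component means no resolved openings. With two or more, the unitary
    amplitude is the mean difference between adjacent peak positions, signed
    in the direction from the closed level toward the open levels. The closed
    level is identified as the component with the largest area (the baseline
    occupies most of the record), which makes the sign insensitive to any
    constant offset of the current axis.
    """
    if fit.n_components < 2:
        return None
    closed = int(np.argmax(fit.areas))  # components are sorted by center
    return peak_difference(fit.centers, closed)


@dataclass(frozen=True)
class UnitaryPoint:
    """Mean unitary amplitude (+/- SE over stretches) at one transmembrane voltage."""

    v_trans: float  # mV
    amplitude: float  # pA
    se: float = 0.0
    n_stretches: int = 1


class UnitaryIVModel:
    """Straight-line model amplitude = gamma * (V_trans - V_rev)."""

    def __init__(self, points: Sequence[UnitaryPoint]) -> None:
        if len({p.v_trans for p in points}) < 2:
            raise ValueError("need unitary amplitudes at >=2 distinct transmembrane voltages")
        self.points = list(points)

    def fit(self) -> "UnitaryIVResults":
        v = np.array([p.v_trans for p in self.points])
        a = np.array([p.amplitude for p in self.points])
        n = len(v)
        (slope, intercept), cov = np.polyfit(v, a, 1, cov=True) if n > 2 else (np.polyfit(v, a, 1), None)
        if cov is None:
            cov = np.zeros((2, 2))
        gamma_ps = slope * 1000.0  # pA/mV = nS -> pS
        v_rev = -intercept / slope if slope != 0 else float("nan")
        var_m, var_b = cov[0, 0], cov[1, 1]
        cov_mb = cov[0, 1]
        gamma_se = np.sqrt(var_m) * 1000.0
        if slope != 0:
            # delta method on -b/m
            v_rev_var = (
                var_b / slope**2
                + intercept**2 * var_m / slope**4
                - 2.0 * intercept * cov_mb / slope**3
            )
            v_rev_se = float(np.sqrt(max(v_rev_var, 0.0)))
        else:
            v_rev_se = float("nan")
        return UnitaryIVResults(
            points=self.points,
            gamma=float(gamma_ps),
            gamma_se=float(gamma_se),
            v_rev=float(v_rev),
            v_rev_se=v_rev_se,
        )


@dataclass
class UnitaryIVResults:
    """Unitary conductance (pS) and reversal potential (mV) from the I/V line."""

    points: list[UnitaryPoint]
    gamma: float
    gamma_se: float
    v_rev: float
    v_rev_se: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    def summary(self) -> str:
        return (
            "Unitary I/V line fit\n"
            f"  gamma = {self.gamma:.2f} +/- {self.gamma_se:.2f} pS\n"
            f"  V_rev = {self.v_rev:.2f} +/- {self.v_rev_se:.2f} mV\n"
            f"  n points = {self.n_points}"
        )

    def to_dict(self) -> dict:
        return {
            "gamma_pS": self.gamma,
            "gamma_se_pS": self.gamma_se,
            "v_rev_mV": self.v_rev,
            "v_rev_se_mV": self.v_rev_se,
            "n_points": self.n_points,
        }


def fit_unitary_iv(points: Sequence[UnitaryPoint]) -> UnitaryIVResults:
    """Least-squares unitary I/V line; conductance from the slope, reversal from the x-intercept."""
    return UnitaryIVModel(points).fit()


def analyze_record(
    record: PatchRecord,
    bin_width: float = 0.02,
    max_n: int = 3,
    min_stretches: int = 3,
) -> UnitaryPoint | None:
    """Per-record reduction: stretch-wise mixtures -> mean unitary amplitude.

    Each 1.9 s stretch is binned and mixture-fitted independently; stretch
    amplitudes are averaged with their SE. A stretch whose amplitude sits
    more than 3 scaled MADs (floored at two bin widths) from the median of
    the stretches is discarded before averaging: an occasional stretch
    resolves a spurious intermediate level and would otherwise corrupt the
    mean. Returns None when no stretch resolves an opening (single-peak
    histograms throughout).
    """
    amps = []
    for stretch in record.stretches():
        hist = bin_amplitudes(stretch, bin_width)
        try:
            fit = fit_mixture(hist, max_n=max_n)
        except (RuntimeError, ValueError):
            continue
        amp = unitary_amplitude(fit)
        if amp is not None:
            amps.append(amp)
    if len(amps) < min_stretches:
        return None
    amps_arr = np.array(amps)
    med = np.median(amps_arr)
    mad = np.median(np.abs(amps_arr - med))
    tol = max(3.0 * 1.4826 * mad, 2.0 * bin_width)
    amps_arr = amps_arr[np.abs(amps_arr - med) <= tol]
    se = float(amps_arr.std(ddof=1) / np.sqrt(len(amps_arr))) if len(amps_arr) > 1 else 0.0
    return UnitaryPoint(
        v_trans=record.v_trans,
        amplitude=float(amps_arr.mean()),
        se=se,
        n_stretches=len(amps_arr),
    )
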