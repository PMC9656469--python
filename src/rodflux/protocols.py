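"""Perfusion protocols for calcium-imaging experiments.

A protocol is an ordered, non-overlapping list of solution applications
(segments). Solution labels cover the depolarizing KCl series, the
calcium-free/EGTA saline, ionomycin in 0 Ca or 30 mM Ca, the calibrated
494 nM calcium saline, caffeine, thapsigargin, the Mn2+ quench reference
and the CSC blocker MRS-1845.
"""

from __future__ import annotations

import enum
import json
from typing import Sequence

from pydantic import BaseModel, model_validator


class Solution(str, enum.Enum):
    """Perfusion solution labels."""

    LOCKE = "LOCKE"
    K10 = "K10"
    K16 = "K16"
    K25 = "K25"
    K40 = "K40"
    ZERO_CA_EGTA = "ZERO_CA_EGTA"
    IONO_0CA = "IONO_0CA"
    IONO_30CA = "IONO_30CA"
    CA_494 = "CA_494"
    CAFFEINE = "CAFFEINE"
    THAPSIGARGIN = "THAPSIGARGIN"
    MN_QUENCH = "MN_QUENCH"
    MRS1845 = "MRS1845"


#: Extracellular [K+]o in mM associated with each depolarizing segment label.
K_LEVELS_MM = {Solution.K10: 10, Solution.K16: 16, Solution.K25: 25, Solution.K40: 40}

#: Default duration of a KCl application (seconds).
K_STEP_DURATION_S = 30.0


class Segment(BaseModel):
    """A single solution application: label, onset (s) and duration (s)."""

    solution: Solution
    onset: float
    duration: float

    @model_validator(mode="after")
    def _check(self) -> "Segment":
        if self.onset < 0:
            raise ValueError("segment onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        return self

    @property
    def end(self) -> float:
        return self.onset + self.duration


class PerfusionProtocol(BaseModel):
    """Ordered, non-overlapping sequence of perfusion segments.

    Between segments the bath is assumed to be normal Locke's solution.
    """

    segments: list[Segment]

    @model_validator(mode="after")
    def _check(self) -> "PerfusionProtocol":
        segs = sorted(self.segments, key=lambda s: s.onset)
        for a, b in zip(segs, segs[1:]):
            if b.onset < a.end - 1e-12:
                raise ValueError(
                    f"segments overlap: {a.solution.value} [{a.onset}, {a.end}) and "
                    f"{b.solution.value} starting at {b.onset}"
                )
        self.segments = segs
        return self

    @property
    def end(self) -> float:
        """Time at which the last segment ends (s)."""
        return max((s.end for s in self.segments), default=0.0)

    def active(self, t: float) -> Solution:
        """Solution present at time ``t`` (Locke's between segments)."""
        for s in self.segments:
            if s.onset <= t < s.end:
                return s.solution
        return Solution.LOCKE

    def find(self, solution: Solution) -> list[Segment]:
        """All segments with the given label, in time order."""
        return [s for s in self.segments if s.solution == solution]

    def require(self, solution: Solution) -> Segment:
        """First segment with the given label; raise if absent."""
        found = self.find(solution)
        if not found:
            raise ValueError(f"protocol contains no {solution.value} segment")
        return found[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [
                    {"solution": s.solution.value, "onset": s.onset, "duration": s.duration}
                    for s in self.segments
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PerfusionProtocol":
        data = json.loads(text)
        return cls(segments=[Segment(**d) for d in data["segments"]])


def kcl_series(
    levels: Sequence[int] = (10, 16, 25, 40),
    first_onset: float = 60.0,
    duration: float = K_STEP_DURATION_S,
    recovery: float = 60.0,
) -> PerfusionProtocol:
    """Standard depolarization series: 30 s KCl steps separated by recovery."""
    by_level = {v: k for k, v in K_LEVELS_MM.items()}
    segs = []
    t = first_onset
    for lv in levels:
        if lv not in by_level:
            raise ValueError(f"no solution label for [K]o = {lv} mM")
        segs.append(Segment(solution=by_level[lv], onset=t, duration=duration))
        t += duration + recovery
    return PerfusionProtocol(segments=segs)


def store_depletion_protocol(
    k_onset: float = 60.0,
    k_duration: float = 20.0,
    recovery: float = 60.0,
    egta_duration: float = 20.0,
    iono_duration: float = 60.0,
) -> PerfusionProtocol:
    """25 mM KCl, recovery, 0 Ca/EGTA, then ionomycin in 0 Ca.

    This is the store-content probing sequence: the drop in 0 Ca/EGTA reports
    the balance between influx block and store release, and the ionomycin
    response in 0 Ca reports the total releasable store content.
    """
    t_egta = k_onset + k_duration + recovery
    return PerfusionProtocol(
        segments=[
            Segment(solution=Solution.K25, onset=k_onset, duration=k_duration),
            Segment(solution=Solution.ZERO_CA_EGTA, onset=t_egta, duration=egta_duration),
            Segment(solution=Solution.IONO_0CA, onset=t_egta + egta_duration, duration=iono_duration),
        ]
    )


def calibration_protocol(
    start: float = 40.0,
    iono0_duration: float = 80.0,
    cal_duration: float = 40.0,
    fmax_duration: float = 40.0,
) -> PerfusionProtocol:
    """Dye-calibration sequence: ionomycin/0 Ca (F0), 494 nM Ca, 30 mM Ca (F_MAX)."""
    t1 = start + iono0_duration
    t2 = t1 + cal_duration
    return PerfusionProtocol(
        segments=[
            Segment(solution=Solution.IONO_0CA, onset=start, duration=iono0_duration),
            Segment(solution=Solution.CA_494, onset=t1, duration=cal_duration),
            Segment(solution=Solution.IONO_30CA, onset=t2, duration=fmax_duration),
        ]
    )


def drug_protocol(
    solution: Solution,
    onset: float = 120.0,
    duration: float = 60.0,
) -> PerfusionProtocol:
    """Single-application protocol (caffeine, MRS-1845, thapsigargin...)."""
    return PerfusionProtocol(segments=[Segment(solution=solution, onset=onset, duration=duration)])
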