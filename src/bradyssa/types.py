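"""Core domain containers: gyroscope recordings, event logs, cohort rows.

Angular velocity is always in degrees per second (deg/s), time in seconds.
A recording holds one single-axis gyroscope trace for one participant, one
game phase, and one medication state; pronation-supination movements rotate
about the sensor's Y axis, so that is the default axis label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import ParameterError

#: Medication states. Healthy controls are never medicated, hence ``NA``.
STATES = ("ON", "OFF", "NA")
#: Cohorts: CG = healthy control group, EG = Parkinson experimental group.
COHORTS = ("CG", "EG")


@dataclass(frozen=True, eq=False)
class GyroRecording:
    """One single-axis angular-velocity time series with its provenance.

    Parameters
    ----------
    participant_id : str
        Identifier such as ``"EG07"``.
    cohort : {"CG", "EG"}
    state : {"ON", "OFF", "NA"}
        Medication state; controls (CG) must use ``"NA"``.
    phase : int
        Game phase, 1–4. Angular-velocity metrics are defined for phase 4
        (forearm pronation-supination) only.
    fs : float
        Sampling rate in Hz.
    samples : numpy.ndarray
        Angular velocity in deg/s.
    axis : str
        Sensor axis label, default ``"Y"``.
    t0 : float
        Start time of the recording in seconds.
    """

    participant_id: str
    cohort: str
    state: str
    phase: int
    fs: float
    samples: np.ndarray
    axis: str = "Y"
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )
        if self.cohort not in COHORTS:
            raise ParameterError(f"unknown cohort {self.cohort!r}")
        if self.state not in STATES:
            raise ParameterError(f"unknown state {self.state!r}")
        if self.cohort == "CG" and self.state != "NA":
            raise ParameterError("CG recordings must have state 'NA'")
        if not 1 <= int(self.phase) <= 4:
            raise ParameterError(f"phase must be 1–4, got {self.phase}")
        if not self.fs > 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must all be finite")

    def __eq__(self, other) -> bool:
        if not isinstance(other, GyroRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.cohort == other.cohort
            and self.state == other.state
            and self.phase == other.phase
            and self.fs == other.fs
            and self.axis == other.axis
            and self.t0 == other.t0
            and np.array_equal(self.samples, other.samples)
        )

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass(frozen=True)
class EventLog:
    """Ordered stimulus-to-completion intervals for one game session.

    Each interval is half-open ``[start_s, end_s)``; its duration is one
    response time (reaction time + movement time).
    """

    participant_id: str
    cohort: str
    state: str
    phase: int
    intervals: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        ivs = tuple(sorted(ivs, key=lambda p: p[0]))
        for i, (a, b) in enumerate(ivs):
            if not b > a:
                raise ParameterError(
                    f"interval {i}: end {b} must exceed start {a}"
                )
            if i and a < ivs[i - 1][1]:
                raise ParameterError(
                    f"interval {i} overlaps the preceding interval"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def durations(self) -> np.ndarray:
        """Per-event durations end − start, in seconds, order preserved."""
        return np.array([b - a for a, b in self.intervals], dtype=float)


@dataclass(frozen=True)
class ParticipantSummary:
    """One cohort-table row: aggregated slowness metrics plus clinical scores.

    ``brad_score`` is the bradykinesia index (sum of MDS-UPDRS items
    3.4a–3.6b); missing values are ``None``, never 0.
    """

    participant_id: str
    cohort: str
    state: str
    age_years: Optional[int] = None
    rt_s: Optional[float] = None
    av_dps: Optional[float] = None
    brad_score: Optional[int] = None
    updrs3_total: Optional[int] = None
    hy_stage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ParameterError(f"unknown cohort {self.cohort!r}")
        if self.state not in STATES:
            raise ParameterError(f"unknown state {self.state!r}")
        if self.rt_s is not None and not self.rt_s > 0:
            raise ParameterError("rt_s must be > 0 when present")
        if self.av_dps is not None and not self.av_dps > 0:
            raise ParameterError("av_dps must be > 0 when present")
        if self.brad_score is not None and not 0 <= self.brad_score <= 24:
            raise ParameterError("brad_score must lie in [0, 24]")
        if self.hy_stage is not None and not 1 <= self.hy_stage <= 5:
            raise ParameterError("hy_stage must lie in [1, 5]")
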