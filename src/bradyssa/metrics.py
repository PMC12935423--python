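"""Slowness metrics: response time from event logs, angular velocity from peaks.

Response time (RT) is the duration of the in-game binary event running from
stimulus onset to movement completion — reaction time plus movement time.
Angular velocity (AV) is the peak rotational speed of the tremor-free
voluntary signal: every local extremum of |angular velocity| above half the
recording's maximum counts as one movement half-cycle (pronation or
supination), and the per-participant AV is the median (or mean) peak
magnitude. AV is defined for game phase 4 only, the phase whose scoring
movement rotates about the measured axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import PairingError, ParameterError
from .types import EventLog

DEFAULT_THRESHOLD_REL = 0.5
DEFAULT_MIN_SEP_S = 0.5

CHANGE_LABELS = ("both_improved", "rt_only", "av_only", "both_worsened")


@dataclass(frozen=True)
class RTSeries:
    """Per-event response times, in seconds, in game order."""

    durations_s: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_s, dtype=float)
        if d.size and not np.all(d > 0):
            raise ParameterError("all durations must be > 0")
        object.__setattr__(self, "durations_s", d)

    @property
    def n_events(self) -> int:
        return int(self.durations_s.size)


@dataclass(frozen=True)
class PeakSet:
    """Detected voluntary-movement peaks of one recording.

    ``magnitudes_dps`` are |angular velocity| values in deg/s;
    ``threshold_rel`` records the relative threshold used (fraction of the
    recording's maximum absolute amplitude).
    """

    indices: np.ndarray
    magnitudes_dps: np.ndarray
    threshold_rel: float
    fs: float

    @property
    def n_peaks(self) -> int:
        return int(self.indices.size)

    def times(self) -> np.ndarray:
        return self.indices / self.fs


def response_times(log: EventLog) -> RTSeries:
    """Per-event RT = end − start for every interval, order preserved."""
    return RTSeries(durations_s=log.durations())


def detect_peaks(voluntary, fs: float,
                 threshold_rel: float = DEFAULT_THRESHOLD_REL,
                 min_sep_s: float = DEFAULT_MIN_SEP_S) -> PeakSet:
    """Find movement-cycle peaks in the voluntary angular-velocity signal.

    Local maxima of ``|voluntary|`` at least ``threshold_rel`` times the
    maximum absolute amplitude, separated by at least ``min_sep_s`` seconds.
    Taking the absolute value makes both pronation and supination
    half-cycles count and renders the result invariant under a sign flip of
    the gyroscope axis.
    """
    x = np.abs(np.asarray(voluntary, dtype=float))
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    if not 0 < threshold_rel <= 1:
        raise ParameterError("threshold_rel must lie in (0, 1]")
    peak = float(x.max()) if x.size else 0.0
    if peak == 0.0:
        return PeakSet(indices=np.array([], dtype=int),
                       magnitudes_dps=np.array([]),
                       threshold_rel=threshold_rel, fs=fs)
    distance = max(1, int(round(min_sep_s * fs)))
    idx, _ = find_peaks(x, height=threshold_rel * peak, distance=distance)
    return PeakSet(indices=idx, magnitudes_dps=x[idx],
                   threshold_rel=threshold_rel, fs=fs)


def summarize_participant(rt: Optional[RTSeries], peaks: Optional[PeakSet],
                          agg: str = "median") -> Dict[str, Optional[float]]:
    """Aggregate per-event RTs and peak magnitudes into one row fragment.

    Returns ``{"rt_s": ..., "av_dps": ..., "agg": agg}``; an empty input
    yields ``None`` for the corresponding metric (never 0).
    """
    if agg not in ("median", "mean"):
        raise ParameterError(f"agg must be 'median' or 'mean', got {agg!r}")
    fn = np.median if agg == "median" else np.mean
    rt_s = (float(fn(rt.durations_s))
            if rt is not None and rt.n_events else None)
    av_dps = (float(fn(peaks.magnitudes_dps))
              if peaks is not None and peaks.n_peaks else None)
    return {"rt_s": rt_s, "av_dps": av_dps, "agg": agg}


def _participant_key(pid: str) -> str:
    # "EG07" and "07" refer to the same participant in paired tables
    return pid.lstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ") or pid


def classify_on_off_change(cohort: pd.DataFrame) -> pd.Series:
    """Label each EG participant's ON-vs-OFF change in RT and AV.

    Improvement means RT strictly lower and/or AV strictly higher in the ON
    state; exact ties count as not-improved. Labels: ``both_improved``,
    ``rt_only``, ``av_only``, ``both_worsened``.

    ``cohort`` must contain paired EG rows (states ON and OFF) with columns
    ``participant_id``, ``state``, ``rt_s``, ``av_dps``.
    """
    eg = cohort[cohort["state"].isin(["ON", "OFF"])]
    by_state = {
        state: frame.set_index(frame["participant_id"].map(_participant_key))
        for state, frame in eg.groupby("state")
    }
    if set(by_state) != {"ON", "OFF"}:
        raise PairingError("need both ON and OFF rows")
    on, off = by_state["ON"], by_state["OFF"]
    unpaired = set(on.index).symmetric_difference(off.index)
    if unpaired:
        raise PairingError(f"unpaired participants: {sorted(unpaired)}")
    labels = {}
    for pid in on.index:
        rt_better = on.loc[pid, "rt_s"] < off.loc[pid, "rt_s"]
        av_better = on.loc[pid, "av_dps"] > off.loc[pid, "av_dps"]
        if rt_better and av_better:
            labels[pid] = "both_improved"
        elif rt_better:
            labels[pid] = "rt_only"
        elif av_better:
            labels[pid] = "av_only"
        else:
            labels[pid] = "both_worsened"
    out = pd.Series(labels, name="change")
    return out.sort_index(key=lambda ix: [(len(p), p) for p in ix])
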