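"""Synthetic gyroscope recordings, event logs, and cohorts with ground truth.

The generator emulates the phase-4 game task: forearm pronation-supination
produces a train of signed raised-cosine angular-velocity lobes
(alternating sign — one lobe per half-cycle, band-limited below the tremor
band) whose peak amplitudes carry the participant's movement speed;
Parkinsonian tremor adds an amplitude-modulated sinusoid in the 4–7 Hz
band; the sensor adds white noise. Event logs are built from lognormal reaction plus lognormal movement
times, so each response time has positive support and right skew. Cohorts
tie a clinical bradykinesia score to the true angular velocity through a
noisy decreasing affine link.

All randomness derives from one root seed through named
``numpy.random.SeedSequence`` substreams, so adding a participant never
perturbs another participant's draws, and every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.signal

from .exceptions import SpecError
from .io import summaries_to_frame
from .types import EventLog, GyroRecording, ParticipantSummary

DEFAULT_FS = 250.0

#: Group mean angular velocities (deg/s) and response times (s) used for the
#: default cohort; recomputed from the published cohort table by
#: :func:`CohortSpec.default` — these module constants exist only as
#: fallbacks and are asserted equal to the table means in the test suite.
_GROUP_AV_MEANS = {"CG": 449.01, "EG-ON": 289.98, "EG-OFF": 250.41}
_GROUP_RT_MEANS = {"CG": 1.73, "EG-ON": 1.94, "EG-OFF": 2.27}


@dataclass(frozen=True)
class MovementSpec:
    """Voluntary pronation-supination burst train.

    Amplitudes in deg/s, times in seconds. ``n_pulses`` raised-cosine
    velocity lobes of width ``pulse_width_s`` are spaced ``inter_pulse_s``
    apart (uniform jitter of ±``inter_pulse_jitter_s``) after a
    ``lead_in_s`` quiet span, then low-passed (zero phase) at
    ``lowpass_hz`` so the voluntary movement is spectrally below the
    tremor band — the premise under which subtracting in-band components
    leaves the voluntary signal intact. The reported ground-truth pulse
    amplitudes are measured on the emitted (filtered) series.
    """

    n_pulses: int = 12
    pulse_amp_mean: float = 300.0
    pulse_amp_sd: float = 25.0
    pulse_width_s: float = 0.45
    inter_pulse_s: float = 0.9
    inter_pulse_jitter_s: float = 0.15
    lead_in_s: float = 1.0
    lowpass_hz: float = 2.8
    lowpass_order: int = 6
    duration_s: Optional[float] = None
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise SpecError("n_pulses must be >= 1")
        if self.pulse_amp_mean <= 0 or self.pulse_amp_sd < 0:
            raise SpecError("pulse amplitudes must be positive")
        if not 0 < self.pulse_width_s < self.inter_pulse_s:
            raise SpecError("pulse_width_s must lie in (0, inter_pulse_s)")
        if self.inter_pulse_jitter_s < 0:
            raise SpecError("inter_pulse_jitter_s must be >= 0")
        if self.fs <= 0:
            raise SpecError("fs must be > 0")
        if not 0 < self.lowpass_hz < self.fs / 2:
            raise SpecError("lowpass_hz must lie in (0, fs/2)")
        if self.duration_s is not None and self.duration_s < self.min_duration_s():
            raise SpecError(
                f"duration {self.duration_s} s cannot hold {self.n_pulses} "
                f"pulses (need >= {self.min_duration_s():.2f} s)")

    def min_duration_s(self) -> float:
        worst_gap = self.inter_pulse_s + self.inter_pulse_jitter_s
        return (self.lead_in_s + self.n_pulses * worst_gap
                + self.pulse_width_s + 0.5)

    def total_duration_s(self) -> float:
        return self.duration_s if self.duration_s is not None \
            else self.min_duration_s()


@dataclass(frozen=True)
class TremorSpec:
    """Amplitude-modulated tremor plus white measurement noise.

    ``freq_hz`` must lie in the Parkinsonian band; ``am_depth`` in [0, 1]
    modulates the envelope at the slow ``am_rate_hz``. When ``rms_ratio``
    is given, ``amp_dps`` is rescaled so the tremor RMS equals that
    fraction of the voluntary-signal RMS.
    """

    freq_hz: float = 5.0
    amp_dps: float = 25.0
    am_depth: float = 0.5
    am_rate_hz: float = 0.4
    noise_sd_dps: float = 3.0
    rms_ratio: Optional[float] = None
    band: Tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        if not self.band[0] <= self.freq_hz <= self.band[1]:
            raise SpecError(
                f"freq_hz {self.freq_hz} outside band {self.band}")
        if self.amp_dps < 0 or self.noise_sd_dps < 0:
            raise SpecError("amplitudes must be >= 0")
        if not 0 <= self.am_depth <= 1:
            raise SpecError("am_depth must lie in [0, 1]")
        if self.rms_ratio is not None and self.rms_ratio < 0:
            raise SpecError("rms_ratio must be >= 0")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_recording(mspec: MovementSpec, tspec: Optional[TremorSpec], seed,
                   participant_id: str = "SIM01", cohort: str = "EG",
                   state: str = "OFF", phase: int = 4
                   ) -> Tuple[GyroRecording, Dict[str, np.ndarray]]:
    """Simulate one phase-4 recording; returns (recording, ground truth).

    Truth carries the noiseless voluntary series, the tremor series, the
    signed pulse peak amplitudes and their times.
    """
    rng = _as_rng(seed)
    fs = mspec.fs
    duration = mspec.total_duration_s()
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # voluntary burst train: signed raised-cosine lobes, alternating sign
    gaps = mspec.inter_pulse_s + mspec.inter_pulse_jitter_s * rng.uniform(
        -1.0, 1.0, size=mspec.n_pulses)
    starts = mspec.lead_in_s + np.concatenate(([0.0], np.cumsum(gaps[:-1])))
    if starts[-1] + mspec.pulse_width_s > duration:
        raise SpecError("pulses overflow the recording duration")
    draw = rng.normal(mspec.pulse_amp_mean, mspec.pulse_amp_sd,
                      size=mspec.n_pulses)
    draw = np.clip(draw, 0.1 * mspec.pulse_amp_mean, None)
    signs = np.where(np.arange(mspec.n_pulses) % 2 == 0, 1.0, -1.0)
    voluntary = np.zeros(n)
    width_n = max(2, int(round(mspec.pulse_width_s * fs)))
    lobe_phase = np.sin(np.pi * np.arange(width_n) / (width_n - 1)) ** 2
    windows = []
    for a, s, start in zip(draw, signs, starts):
        i0 = int(round(start * fs))
        i1 = min(n, i0 + width_n)
        voluntary[i0:i1] += a * s * lobe_phase[: i1 - i0]
        windows.append((i0, i1))
    # confine the voluntary movement spectrally below the tremor band
    b, a_coef = scipy.signal.butter(
        mspec.lowpass_order, mspec.lowpass_hz / (fs / 2))
    voluntary = scipy.signal.filtfilt(b, a_coef, voluntary)
    # ground-truth peak amplitude of each lobe, measured on the emitted series
    amps = np.array([np.max(np.abs(voluntary[i0:i1]))
                     for i0, i1 in windows])

    tremor = np.zeros(n)
    noise = np.zeros(n)
    if tspec is not None:
        carrier_phase = rng.uniform(0, 2 * np.pi)
        am_phase = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + tspec.am_depth * np.sin(
            2 * np.pi * tspec.am_rate_hz * t + am_phase)
        envelope /= 1.0 + tspec.am_depth
        tremor = tspec.amp_dps * envelope * np.sin(
            2 * np.pi * tspec.freq_hz * t + carrier_phase)
        if tspec.rms_ratio is not None:
            target = tspec.rms_ratio * float(np.sqrt(np.mean(voluntary**2)))
            rms = float(np.sqrt(np.mean(tremor**2)))
            tremor = tremor * (target / rms) if rms > 0 else tremor
        if tspec.noise_sd_dps > 0:
            noise = rng.normal(0.0, tspec.noise_sd_dps, size=n)

    recording = GyroRecording(
        participant_id=participant_id, cohort=cohort, state=state,
        phase=phase, fs=fs, samples=voluntary + tremor + noise)
    truth = {
        "voluntary": voluntary,
        "tremor": tremor,
        "noise": noise,
        "pulse_amplitudes": amps,
        "pulse_signs": signs,
        "pulse_times_s": starts + mspec.pulse_width_s / 2,
    }
    return recording, truth


@dataclass(frozen=True)
class RTSpec:
    """Lognormal reaction- and movement-time components of one response.

    ``reaction`` and ``movement`` are ``(mu, sigma)`` parameters of the
    underlying normals, in log-seconds.
    """

    reaction: Tuple[float, float] = (np.log(0.5), 0.25)
    movement: Tuple[float, float] = (np.log(1.2), 0.25)

    def __post_init__(self) -> None:
        for name, (mu, sig) in (("reaction", self.reaction),
                                ("movement", self.movement)):
            if sig < 0 or not np.isfinite(mu):
                raise SpecError(f"invalid {name} parameters ({mu}, {sig})")

    @classmethod
    def from_median_rt(cls, rt_median_s: float, reaction_share: float = 0.35,
                       sigma: float = 0.25) -> "RTSpec":
        """Spec whose component medians sum to ``rt_median_s``."""
        if rt_median_s <= 0:
            raise SpecError("rt_median_s must be > 0")
        return cls(
            reaction=(float(np.log(reaction_share * rt_median_s)), sigma),
            movement=(float(np.log((1 - reaction_share) * rt_median_s)),
                      sigma),
        )


def make_event_log(n_events: int, rtspec: RTSpec, seed,
                   participant_id: str = "SIM01", cohort: str = "EG",
                   state: str = "OFF", phase: int = 4,
                   start_s: float = 5.0, gap_s: Tuple[float, float] = (2.0, 4.0)
                   ) -> Tuple[EventLog, np.ndarray]:
    """Simulate one game session's event log; returns (log, true durations)."""
    if n_events < 1:
        raise SpecError("n_events must be >= 1")
    rng = _as_rng(seed)
    reaction = rng.lognormal(*rtspec.reaction, size=n_events)
    movement = rng.lognormal(*rtspec.movement, size=n_events)
    durations = reaction + movement
    gaps = rng.uniform(gap_s[0], gap_s[1], size=n_events)
    intervals = []
    cursor = start_s
    for dur, gap in zip(durations, gaps):
        intervals.append((cursor, cursor + dur))
        cursor += dur + gap
    log = EventLog(participant_id=participant_id, cohort=cohort, state=state,
                   phase=phase, intervals=tuple(intervals))
    # ground truth is what the log encodes, bit-for-bit: the parsed
    # durations, not the pre-placement draws (which differ by rounding)
    return log, log.durations()


@dataclass(frozen=True)
class GroupParams:
    """Per-group generating parameters for the cohort simulator."""

    av_mean_dps: float
    rt_median_s: float
    av_between_sd_dps: float = 70.0
    av_within_cv: float = 0.08
    tremor: Optional[TremorSpec] = None


@dataclass(frozen=True)
class CohortSpec:
    """Full-cohort generating conditions (defaults mirror the study groups).

    Angular velocity ordering CG > EG-ON > EG-OFF and response-time
    ordering CG < EG-ON < EG-OFF, with group means taken from the
    published cohort table. The bradykinesia score is generated as
    ``round(brad_intercept + brad_slope * true_av + noise)`` clipped to
    [0, 24] — a decreasing affine link whose noise level sets the strength
    of the score-AV rank correlation.
    """

    n_per_group: int = 15
    groups: Dict[str, GroupParams] = field(default_factory=dict)
    n_events: int = 10
    fs: float = DEFAULT_FS
    movement: MovementSpec = MovementSpec()
    brad_intercept: float = 14.5
    brad_slope: float = -0.03
    brad_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise SpecError("n_per_group must be >= 3")
        if not self.groups:
            object.__setattr__(self, "groups", _default_groups())
        if set(self.groups) != {"CG", "EG-ON", "EG-OFF"}:
            raise SpecError("groups must be exactly CG, EG-ON, EG-OFF")


def _default_groups(av_means: Optional[Dict[str, float]] = None,
                    rt_means: Optional[Dict[str, float]] = None
                    ) -> Dict[str, GroupParams]:
    av = av_means or _GROUP_AV_MEANS
    rt = rt_means or _GROUP_RT_MEANS
    tremor_on = TremorSpec(freq_hz=5.2, amp_dps=15.0)
    tremor_off = TremorSpec(freq_hz=5.2, amp_dps=35.0)
    return {
        "CG": GroupParams(av_mean_dps=av["CG"], rt_median_s=rt["CG"],
                          tremor=None),
        "EG-ON": GroupParams(av_mean_dps=av["EG-ON"],
                             rt_median_s=rt["EG-ON"], tremor=tremor_on),
        "EG-OFF": GroupParams(av_mean_dps=av["EG-OFF"],
                              rt_median_s=rt["EG-OFF"], tremor=tremor_off),
    }


def default_cohort_spec(n_per_group: int = 15, seed: int = 0) -> CohortSpec:
    """Cohort spec whose group means are recomputed from the printed table."""
    from .tables import fixture_table2

    t2 = fixture_table2()
    av_means, rt_means = {}, {}
    for label, mask in (
        ("CG", t2["cohort"] == "CG"),
        ("EG-ON", (t2["cohort"] == "EG") & (t2["state"] == "ON")),
        ("EG-OFF", (t2["cohort"] == "EG") & (t2["state"] == "OFF")),
    ):
        av_means[label] = float(t2.loc[mask, "av_dps"].mean())
        rt_means[label] = float(t2.loc[mask, "rt_s"].mean())
    return CohortSpec(n_per_group=n_per_group, seed=seed,
                      groups=_default_groups(av_means, rt_means))


_GROUP_CODES = {"CG": 0, "EG-ON": 1, "EG-OFF": 2, "EG": 9}
_STREAMS = {"recording": 0, "events": 1, "clinical": 2, "participant": 3}


def _substream(root: int, group: str, participant: int, stream: str
               ) -> np.random.Generator:
    seq = np.random.SeedSequence(
        [int(root), _GROUP_CODES[group], participant, _STREAMS[stream]])
    return np.random.default_rng(seq)


@dataclass
class CohortBundle:
    """Everything the simulator emits for one cohort draw."""

    spec: CohortSpec
    recordings: Dict[Tuple[str, str], GyroRecording]
    event_logs: Dict[Tuple[str, str], EventLog]
    cohort: pd.DataFrame
    truth: pd.DataFrame
    signal_truth: Dict[Tuple[str, str], Dict[str, np.ndarray]]


def make_cohort(cspec: CohortSpec) -> CohortBundle:
    """Simulate recordings, event logs, and the cohort table with truth.

    For each participant and state one phase-4 recording and one event log
    are generated. The returned ``cohort`` frame contains the *true*
    aggregate values (median pulse amplitude, median event duration) — the
    signal pipeline's job is to recover them; ``truth`` repeats them with
    the generating parameters for recovery tests.
    """
    recordings: Dict[Tuple[str, str], GyroRecording] = {}
    event_logs: Dict[Tuple[str, str], EventLog] = {}
    signal_truth: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    summary_rows: List[ParticipantSummary] = []
    truth_rows: List[Dict] = []
    for group, params in cspec.groups.items():
        cohort_label = "CG" if group == "CG" else "EG"
        state = "NA" if group == "CG" else group.split("-")[1]
        for p in range(1, cspec.n_per_group + 1):
            pid = f"{cohort_label}{p:02d}"
            prng = _substream(cspec.seed, group, p, "participant")
            if cohort_label == "EG":
                # paired design: one participant random effect shared by the
                # ON and OFF recordings, plus a small state-level jitter
                shared = _substream(cspec.seed, "EG", p, "participant")
                effect = shared.normal(0.0, params.av_between_sd_dps)
                jitter = prng.normal(0.0, 15.0)
                amp = float(np.clip(
                    params.av_mean_dps + effect + jitter, 120.0, None))
            else:
                amp = float(np.clip(
                    prng.normal(params.av_mean_dps,
                                params.av_between_sd_dps),
                    120.0, None))
            mspec = replace(
                cspec.movement, fs=cspec.fs, pulse_amp_mean=amp,
                pulse_amp_sd=params.av_within_cv * amp)
            rec, rec_truth = make_recording(
                mspec, params.tremor,
                _substream(cspec.seed, group, p, "recording"),
                participant_id=pid, cohort=cohort_label, state=state)
            rtspec = RTSpec.from_median_rt(params.rt_median_s)
            log, durations = make_event_log(
                cspec.n_events, rtspec,
                _substream(cspec.seed, group, p, "events"),
                participant_id=pid, cohort=cohort_label, state=state)
            key = (pid, state)
            recordings[key] = rec
            event_logs[key] = log
            signal_truth[key] = rec_truth
            true_av = float(np.median(rec_truth["pulse_amplitudes"]))
            true_rt = float(np.median(durations))
            brad = None
            if cohort_label == "EG":
                crng = _substream(cspec.seed, group, p, "clinical")
                raw = (cspec.brad_intercept + cspec.brad_slope * true_av
                       + crng.normal(0.0, cspec.brad_noise_sd))
                brad = int(np.clip(round(raw), 0, 24))
            summary_rows.append(ParticipantSummary(
                participant_id=pid, cohort=cohort_label, state=state,
                rt_s=true_rt, av_dps=true_av, brad_score=brad))
            truth_rows.append({
                "participant_id": pid, "group": group, "state": state,
                "true_median_pulse_amp_dps": true_av,
                "true_median_rt_s": true_rt,
                "tremor_freq_hz": (params.tremor.freq_hz
                                   if params.tremor else None),
                "brad_score": brad,
            })
    return CohortBundle(
        spec=cspec, recordings=recordings, event_logs=event_logs,
        cohort=summaries_to_frame(summary_rows),
        truth=pd.DataFrame(truth_rows),
        signal_truth=signal_truth,
    )
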