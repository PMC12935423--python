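"""Splitting a gyroscope recording into voluntary movement and tremor.

Parkinsonian rest tremor appears in forearm gyroscope traces as a 4–7 Hz
oscillation superimposed on the much slower voluntary pronation-supination
bursts. In the SSA decomposition a (possibly amplitude-modulated) sinusoid
shows up as adjacent eigentriple *pairs* with near-equal singular values and
strong mutual w-correlation. The separator finds such pairs automatically,
keeps only those whose reconstructed component is spectrally inside the
tremor band, merges them into one "tremor" group, and subtracts the
reconstructed tremor from the recording; the remainder is the voluntary
movement, so voluntary + tremor always reproduces the input exactly.

:class:`TremorSeparation` is the model object; ``fit()`` returns a
:class:`SeparationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import welch

from .exceptions import LengthError, ParameterError
from .ssa import SSA, Grouping, SSADecomposition, default_window
from .types import GyroRecording

#: Parkinsonian tremor band (Hz), endpoints inclusive.
DEFAULT_BAND = (4.0, 7.0)
#: sigma_{i+1} must be within this fraction of sigma_i for a pair.
DEFAULT_PAIR_TOL = 0.2
#: Minimum |w-correlation| between the two members of a pair.
DEFAULT_WCOR_MIN = 0.5
#: Pairs are searched among at most this many leading eigentriples.
MAX_SEARCH_RANK = 30


@dataclass(frozen=True)
class SpectralSummary:
    """Averaged-periodogram density of one series.

    ``band_fraction`` is the fraction of total power falling inside the
    queried band (endpoints inclusive); ``dominant_hz`` the frequency of the
    density maximum (0 for an all-zero series).
    """

    freqs: np.ndarray
    power: np.ndarray
    dominant_hz: float
    band_fraction: float
    band: Tuple[float, float]


def spectrum(series, fs: float,
             band: Tuple[float, float] = DEFAULT_BAND) -> SpectralSummary:
    """Welch power spectral density with a band-power summary.

    Uses Hann-windowed segments of ``min(N, 2 * fs)`` samples with 50%
    overlap, giving a frequency resolution of at most 0.5 Hz for recordings
    of two seconds or longer.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    lo, hi = band
    if lo >= hi:
        raise ParameterError(f"empty band {band}")
    nperseg = int(min(x.size, 2 * fs))
    freqs, power = welch(x, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2, detrend=False)
    total = float(power.sum())
    if total <= 0:
        return SpectralSummary(freqs=freqs, power=power, dominant_hz=0.0,
                               band_fraction=0.0, band=(lo, hi))
    in_band = (freqs >= lo) & (freqs <= hi)
    return SpectralSummary(
        freqs=freqs, power=power,
        dominant_hz=float(freqs[int(np.argmax(power))]),
        band_fraction=float(power[in_band].sum() / total),
        band=(lo, hi),
    )


def find_tremor_groups(model: SSADecomposition, fs: float,
                       band: Tuple[float, float] = DEFAULT_BAND,
                       pair_tol: float = DEFAULT_PAIR_TOL,
                       wcor_min: float = DEFAULT_WCOR_MIN,
                       max_rank: int = MAX_SEARCH_RANK) -> Grouping:
    """Select the eigentriples carrying in-band oscillation.

    A pair (i, i+1) of adjacent eigentriples is accepted when all of:

    * singular-value similarity: ``sigma_{i+1} / sigma_i >= 1 - pair_tol``;
    * mutual |w-correlation| ``>= wcor_min``;
    * the dominant frequency of the pair's reconstructed component lies in
      ``band`` (endpoints inclusive).

    Accepted pairs are unioned into a single "tremor" group (overlapping
    pairs share indices, counted once); the group may be empty.
    """
    lo, hi = band
    if lo >= hi:
        raise ParameterError(f"empty band {band}")
    if hi > fs / 2:
        raise ParameterError(f"band upper edge {hi} exceeds Nyquist {fs / 2}")
    if model.d == 0:
        return Grouping(groups={"tremor": ()})
    kmax = min(model.d, max_rank)
    wcor = model.w_correlation(kmax)
    selected: set = set()
    for i in range(kmax - 1):  # 0-based; pair is eigentriples i+1, i+2
        if model.sigma[i] <= 0:
            break
        if model.sigma[i + 1] / model.sigma[i] < 1.0 - pair_tol:
            continue
        if abs(wcor[i, i + 1]) < wcor_min:
            continue
        pair = model.elementary(i + 1) + model.elementary(i + 2)
        dom = spectrum(pair, fs, band).dominant_hz
        if lo <= dom <= hi:
            selected.update((i + 1, i + 2))
    return Grouping(groups={"tremor": tuple(sorted(selected))})


@dataclass(frozen=True)
class SeparationResult:
    """Voluntary/tremor split of one recording.

    ``voluntary + tremor`` equals the input samples exactly. ``accepted``
    is False when no in-band oscillatory eigentriple pair was found, in
    which case ``tremor`` is identically zero.
    """

    recording: GyroRecording
    voluntary: np.ndarray
    tremor: np.ndarray
    tremor_grouping: Grouping
    tremor_spectrum: SpectralSummary
    accepted: bool
    model: SSADecomposition

    def summary(self) -> str:
        idx = self.tremor_grouping.groups.get("tremor", ())
        lines = [
            f"Tremor separation — participant {self.recording.participant_id}"
            f" ({self.recording.cohort}/{self.recording.state},"
            f" phase {self.recording.phase})",
            f"  samples: {self.recording.n} @ {self.recording.fs:g} Hz,"
            f" SSA window L = {self.model.L}",
            f"  tremor eigentriples: {list(idx) if idx else 'none'}",
            f"  accepted: {self.accepted}",
        ]
        if self.accepted:
            rms = float(np.sqrt(np.mean(self.tremor**2)))
            lines.append(
                f"  tremor dominant frequency: "
                f"{self.tremor_spectrum.dominant_hz:.2f} Hz"
                f" (band {self.tremor_spectrum.band[0]:g}-"
                f"{self.tremor_spectrum.band[1]:g} Hz,"
                f" band fraction {self.tremor_spectrum.band_fraction:.2f})")
            lines.append(f"  tremor RMS: {rms:.2f} deg/s")
        return "\n".join(lines)


class TremorSeparation:
    """Model: SSA-based tremor/voluntary split of one :class:`GyroRecording`.

    Parameters
    ----------
    recording : GyroRecording
    band : (float, float)
        Tremor frequency band in Hz, default (4, 7), endpoints inclusive.
    L, neig : int, optional
        SSA window length and eigentriple cap (see :class:`bradyssa.ssa.SSA`).
    pair_tol, wcor_min : float
        Pair-selection thresholds of :func:`find_tremor_groups`.
    """

    #: Shortest series accepted, as a multiple of the window length.
    MIN_LEN_FACTOR = 2

    def __init__(self, recording: GyroRecording,
                 band: Tuple[float, float] = DEFAULT_BAND,
                 L: Optional[int] = None, neig: Optional[int] = None,
                 pair_tol: float = DEFAULT_PAIR_TOL,
                 wcor_min: float = DEFAULT_WCOR_MIN,
                 max_rank: int = MAX_SEARCH_RANK):
        self.recording = recording
        self.band = (float(band[0]), float(band[1]))
        if self.band[0] >= self.band[1]:
            raise ParameterError(f"empty band {band}")
        if self.band[1] > recording.fs / 2:
            raise ParameterError("band upper edge exceeds Nyquist frequency")
        self.L = L if L is not None else default_window(
            recording.n, recording.fs)
        if recording.n < self.MIN_LEN_FACTOR * self.L:
            raise LengthError(
                f"series of {recording.n} samples is shorter than "
                f"{self.MIN_LEN_FACTOR} windows of L={self.L}")
        self.neig = neig
        self.pair_tol = pair_tol
        self.wcor_min = wcor_min
        self.max_rank = max_rank

    def fit(self) -> SeparationResult:
        model = SSA(self.recording.samples, L=self.L, neig=self.neig).fit()
        grouping = find_tremor_groups(
            model, self.recording.fs, self.band,
            pair_tol=self.pair_tol, wcor_min=self.wcor_min,
            max_rank=self.max_rank)
        idx = grouping.groups["tremor"]
        if idx:
            comps = model.reconstruct(grouping)
            tremor = comps["tremor"]
        else:
            tremor = np.zeros(self.recording.n)
        voluntary = self.recording.samples - tremor
        return SeparationResult(
            recording=self.recording,
            voluntary=voluntary,
            tremor=tremor,
            tremor_grouping=grouping,
            tremor_spectrum=spectrum(tremor, self.recording.fs, self.band),
            accepted=bool(idx),
            model=model,
        )


def separate(recording: GyroRecording,
             band: Tuple[float, float] = DEFAULT_BAND,
             **kwargs) -> SeparationResult:
    """Functional shorthand for ``TremorSeparation(recording, band).fit()``."""
    return TremorSeparation(recording, band=band, **kwargs).fit()
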