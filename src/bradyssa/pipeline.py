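"""One-shot orchestration: simulate/ingest → separate → metrics → stats.

Two entry modes exist because the study's raw recordings are unavailable
while its cohort table is printed in full:

* **full-signal mode** — start from gyroscope and event CSVs (or a
  simulated cohort), separate tremor, detect peaks, aggregate, then run
  the statistical battery;
* **table-only mode** — start from a precomputed cohort CSV and run the
  battery directly, which reproduces every table-derived number without
  raw signals.

``run()`` is deterministic given the config and seed; the report JSON
carries the package version, a config echo, per-stage timings, and every
test/correlation result.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from .io import (read_cohort_csv, read_event_csv, read_gyro_csv,
                 write_cohort_csv)
from .metrics import (DEFAULT_MIN_SEP_S, DEFAULT_THRESHOLD_REL, detect_peaks,
                      response_times, summarize_participant)
from .separation import DEFAULT_BAND, TremorSeparation
from .simulate import default_cohort_spec, make_cohort
from .stats import ALPHA, SlownessAnalysis, SlownessResults
from .types import GyroRecording


@dataclass(frozen=True)
class RunConfig:
    """Every knob of one pipeline run.

    Exactly one of ``simulate``, ``signal_dir``, or ``cohort_csv`` selects
    the input mode: simulated cohort, raw signal/event CSVs, or a
    precomputed cohort table.
    """

    simulate: bool = False
    n_per_group: int = 15
    signal_dir: Optional[Path] = None
    event_dir: Optional[Path] = None
    cohort_csv: Optional[Path] = None
    band: Tuple[float, float] = DEFAULT_BAND
    L: Optional[int] = None
    neig: Optional[int] = None
    peak_threshold: float = DEFAULT_THRESHOLD_REL
    min_sep_s: float = DEFAULT_MIN_SEP_S
    agg: str = "median"
    alpha: float = ALPHA
    seed: int = 0
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        modes = sum(bool(x) for x in
                    (self.simulate, self.signal_dir, self.cohort_csv))
        if modes != 1:
            raise ParameterError(
                "exactly one of simulate / signal_dir / cohort_csv required")
        if self.band[0] >= self.band[1]:
            raise ParameterError(f"empty band {self.band}")
        if not 0 < self.peak_threshold <= 1:
            raise ParameterError("peak_threshold must lie in (0, 1]")
        if self.agg not in ("median", "mean"):
            raise ParameterError("agg must be 'median' or 'mean'")
        for p in (self.signal_dir, self.event_dir, self.cohort_csv):
            if p is not None and not Path(p).exists():
                raise ParameterError(f"path does not exist: {p}")


@dataclass
class RunReport:
    """Per-participant summaries plus the statistical battery's results."""

    config: RunConfig
    cohort: pd.DataFrame
    results: SlownessResults
    separations: List[Dict]
    timings_s: Dict[str, float]

    def to_dict(self, include_timings: bool = True) -> Dict:
        cfg = dataclasses.asdict(self.config)
        for k, v in cfg.items():
            if isinstance(v, Path):
                cfg[k] = str(v)
        payload = {
            "package_version": __version__,
            "config": cfg,
            "cohort": json.loads(
                self.cohort.to_json(orient="records", double_precision=10)),
            "separations": self.separations,
            "stats": {
                "omnibus": {
                    m: dataclasses.asdict(r)
                    for m, r in self.results.omnibus.items()},
                "pairwise": {
                    m: [dataclasses.asdict(r) for r in rs]
                    for m, rs in self.results.pairwise.items()},
                "normality": self.results.normality,
                "correlations": {
                    k: dataclasses.asdict(c)
                    for k, c in self.results.correlations.items()},
                "on_off_change": self.results.on_off_change.to_dict(),
            },
        }
        if include_timings:
            payload["timings_s"] = self.timings_s
        return payload

    def to_json(self, include_timings: bool = True) -> str:
        return json.dumps(self.to_dict(include_timings=include_timings),
                          indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _collect_signal_inputs(config: RunConfig):
    """Load (recording, event log) pairs from the signal/event directories."""
    signal_dir = Path(config.signal_dir)
    event_dir = Path(config.event_dir or config.signal_dir)
    recordings, logs = {}, {}
    for path in sorted(signal_dir.glob("*signal*.csv")):
        rec = read_gyro_csv(path)
        recordings[(rec.participant_id, rec.state)] = rec
    for path in sorted(event_dir.glob("*events*.csv")):
        log = read_event_csv(path)
        logs[(log.participant_id, log.state)] = log
    if not recordings:
        raise ParameterError(f"no '*signal*.csv' files under {signal_dir}")
    return recordings, logs


def run(config: RunConfig) -> RunReport:
    """Execute the configured pipeline and return the full report."""
    timings: Dict[str, float] = {}
    separations: List[Dict] = []
    t0 = time.perf_counter()

    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
        timings["ingest"] = time.perf_counter() - t0
    else:
        if config.simulate:
            spec = default_cohort_spec(n_per_group=config.n_per_group,
                                       seed=config.seed)
            bundle = make_cohort(spec)
            recordings, logs = bundle.recordings, bundle.event_logs
            brad = {
                (r["participant_id"], r["state"]): r["brad_score"]
                for _, r in bundle.cohort.iterrows()}
        else:
            recordings, logs = _collect_signal_inputs(config)
            brad = {}
        timings["ingest"] = time.perf_counter() - t0

        t1 = time.perf_counter()
        rows = []
        for key in sorted(recordings):
            rec = recordings[key]
            try:
                sep = TremorSeparation(
                    rec, band=config.band, L=config.L,
                    neig=config.neig).fit()
            except Exception as exc:
                raise type(exc)(
                    f"separation stage failed for participant "
                    f"{rec.participant_id} ({rec.state}): {exc}") from exc
            separations.append({
                "participant_id": rec.participant_id,
                "state": rec.state,
                "accepted": sep.accepted,
                "tremor_indices": list(
                    sep.tremor_grouping.groups["tremor"]),
                "tremor_dominant_hz": sep.tremor_spectrum.dominant_hz,
            })
            peaks = detect_peaks(sep.voluntary, rec.fs,
                                 threshold_rel=config.peak_threshold,
                                 min_sep_s=config.min_sep_s)
            rt = response_times(logs[key]) if key in logs else None
            frag = summarize_participant(rt, peaks, agg=config.agg)
            b = brad.get(key)
            rows.append({
                "participant_id": rec.participant_id,
                "cohort": rec.cohort, "state": rec.state,
                "age_years": None,
                "rt_s": frag["rt_s"], "av_dps": frag["av_dps"],
                "brad_score": None if b is None or pd.isna(b) else int(b),
                "updrs3_total": None, "hy_stage": None,
            })
        cohort = pd.DataFrame(rows)
        timings["separate_metrics"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    results = SlownessAnalysis(cohort, alpha=config.alpha).fit()
    timings["stats"] = time.perf_counter() - t2

    report = RunReport(config=config, cohort=cohort, results=results,
                       separations=separations, timings_s=timings)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, out / "cohort.csv")
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report
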