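"""Rule-based segmentation of pulse streams into candidate events.

Two independent branches operate on the same stream:

* the **click-train branch** removes echo reflections (< 2 ms after the
  last kept pulse), splits at inter-pulse gaps > 100 ms, and tests nine
  criteria on every resulting segment (pulse count, interval CV, mean
  sound-pressure ratio A/B, duration, spread of the stereo arrival-time
  difference, SPL CV, median interval);
* the **vessel branch** runs on the raw stream, splits at gaps >= 500 ms,
  and requires > 80 consecutive pulses spanning >= 10 s.

Segments are tested as cut, never re-split: a segment spoiled by a stray
background pulse is reported as failed.  False negatives and positives at
this stage are tolerated by design -- downstream classification (or manual
review) is the stage that removes them.  Boundary semantics follow the
criteria exactly: >=/<= are inclusive, </> exclusive, so an interval of
exactly 100 ms stays inside a click train while a 500 ms gap splits a
vessel event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from pulsetrain.pulse_io import PulseSeries

__all__ = [
    "CLICK_CRITERION_NAMES",
    "VESSEL_CRITERION_NAMES",
    "ClickTrainCriteria",
    "VesselCriteria",
    "CandidateEvent",
    "remove_reflections",
    "segment_by_gap",
    "evaluate_clicktrain_criteria",
    "detect_click_trains",
    "detect_vessel_events",
    "passed_events",
    "events_to_frame",
]

#: Flag names for the nine click-train criteria, in table order.
CLICK_CRITERION_NAMES = (
    "min_pulse_interval",
    "max_pulse_interval",
    "min_pulses",
    "cv_pulse_interval",
    "splr",
    "duration",
    "sd_td",
    "cv_spl_a",
    "median_pulse_interval",
)

#: Flag names for the three vessel-noise criteria.
VESSEL_CRITERION_NAMES = ("max_pulse_interval", "min_pulses", "duration")


@dataclass(frozen=True)
class ClickTrainCriteria:
    """Thresholds of the nine click-train criteria.

    Defaults are the operational values for narrow-ridged finless
    porpoise click trains.  ``max_cv_spl_pct`` is a coefficient of
    variation expressed in percent (SD/mean x 100), so the default bound
    of 100 means "SD of hydrophone-A SPL at most equal to its mean".

    ``splr_mode`` selects how the sound-pressure-ratio criterion is
    applied: ``"mean"`` tests the segment mean of the per-pulse linear
    ratio spl_a/spl_b (the ratio is a property of the train), while
    ``"all_pulses"`` requires every individual pulse to satisfy it.
    """

    min_pi_ms: float = 2.0  #: reflections arrive closer than this (inclusive keep)
    max_pi_ms: float = 100.0  #: gap > this splits trains (inclusive stay)
    min_pulses: int = 6
    max_cv_pi: float = 0.4  #: SD/mean of intervals, inclusive
    min_splr: float = 0.6  #: mean spl_a/spl_b, inclusive
    min_duration_ms: float = 12.0  #: inclusive
    max_sd_td_us: float = 25.0  #: exclusive
    max_cv_spl_pct: float = 100.0  #: SD/mean of spl_a in percent, inclusive
    max_median_pi_ms: float = 100.0  #: exclusive
    splr_mode: Literal["mean", "all_pulses"] = "mean"

    def __post_init__(self) -> None:
        numeric = [
            f.name
            for f in fields(self)
            if f.name != "splr_mode"
        ]
        for name in numeric:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.min_pi_ms < self.max_pi_ms:
            raise ValueError("min_pi_ms must be < max_pi_ms")


@dataclass(frozen=True)
class VesselCriteria:
    """Thresholds of the three vessel-noise criteria."""

    max_pi_ms: float = 500.0  #: gap >= this splits events (exclusive stay)
    min_pulses: int = 81  #: i.e. strictly more than 80 pulses
    min_duration_s: float = 10.0  #: inclusive

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class CandidateEvent:
    """Contiguous pulse segment emitted by a rule-based filter.

    ``start_index``/``stop_index`` index into the series the branch was
    evaluated on (the reflection-cleaned series for the click branch,
    the raw series for the vessel branch); ``stop_index`` is exclusive.
    """

    kind: Literal["clicktrain", "vessel"]
    start_index: int
    stop_index: int
    t_start_ms: float
    t_end_ms: float
    criterion_flags: dict

    @property
    def n_pulses(self) -> int:
        return self.stop_index - self.start_index

    @property
    def passed(self) -> bool:
        return all(self.criterion_flags.values())


def remove_reflections(series: PulseSeries, min_pi_ms: float = 2.0) -> PulseSeries:
    """Drop presumed surface/bottom reflections from a pulse stream.

    Left-to-right sweep keeping a pulse iff its time minus the last
    *kept* pulse's time is >= ``min_pi_ms``; the first pulse is always
    kept.  A reflection arrives after its source pulse, so the earlier
    pulse of a close pair is retained.  Idempotent.
    """
    t = series.t_ms
    n = len(t)
    if n == 0:
        return series
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    last = t[0]
    for i in range(1, n):
        if t[i] - last >= min_pi_ms:
            keep[i] = True
            last = t[i]
    if keep.all():
        return series
    return PulseSeries(
        series.t_ms[keep],
        series.spl_a[keep],
        series.spl_b[keep],
        series.td_us[keep],
        start_datetime=series.start_datetime,
        threshold_db=series.threshold_db,
        meta=series.meta,
    )


def segment_by_gap(
    series: PulseSeries,
    threshold_ms: float,
    boundary: Literal["exceeds", "at_or_exceeds"] = "exceeds",
) -> list[tuple[int, int]]:
    """Partition a series into contiguous segments at large inter-pulse gaps.

    ``boundary="exceeds"`` splits where an interval is strictly greater
    than ``threshold_ms`` (click branch: an interval of exactly the
    threshold stays inside one segment); ``"at_or_exceeds"`` splits
    where the interval reaches the threshold (vessel branch).  Returns
    ``(start, stop)`` half-open index pairs that partition the series.
    """
    n = len(series)
    if n == 0:
        return []
    gaps = np.diff(series.t_ms)
    if boundary == "exceeds":
        cut = gaps > threshold_ms
    elif boundary == "at_or_exceeds":
        cut = gaps >= threshold_ms
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown boundary rule {boundary!r}")
    starts = np.concatenate(([0], np.flatnonzero(cut) + 1))
    stops = np.concatenate((starts[1:], [n]))
    return list(zip(starts.tolist(), stops.tolist()))


def _sample_sd(values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator); NaN for n < 2."""
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1))


def evaluate_clicktrain_criteria(
    segment: PulseSeries, criteria: ClickTrainCriteria = ClickTrainCriteria()
) -> dict:
    """Evaluate the nine click-train criteria on one contiguous segment.

    The segment is assumed to come from a click-branch segmentation, so
    the two structural criteria (minimum and maximum pulse interval)
    hold by construction and are reported as ``True``.  Intervals are
    successive time differences; CVs are sample SD / mean (SPL CV in
    percent); duration is last minus first pulse time; the SPLR flag
    uses the segment mean of the per-pulse linear ratio spl_a/spl_b
    (or every pulse individually under ``splr_mode="all_pulses"``).
    Statistics undefined on segments with fewer than two pulses fail.
    """
    n = len(segment)
    flags = {"min_pulse_interval": True, "max_pulse_interval": True}
    flags["min_pulses"] = n >= criteria.min_pulses

    intervals = np.diff(segment.t_ms)
    if len(intervals) >= 1:
        sd_pi = _sample_sd(intervals)
        mean_pi = float(np.mean(intervals))
        flags["cv_pulse_interval"] = (
            not np.isnan(sd_pi) and sd_pi / mean_pi <= criteria.max_cv_pi
        )
        flags["median_pulse_interval"] = (
            float(np.median(intervals)) < criteria.max_median_pi_ms
        )
    else:
        flags["cv_pulse_interval"] = False
        flags["median_pulse_interval"] = False

    splr = segment.spl_a / segment.spl_b if n else np.empty(0)
    if n == 0:
        flags["splr"] = False
    elif criteria.splr_mode == "all_pulses":
        flags["splr"] = bool(np.all(splr >= criteria.min_splr))
    else:
        flags["splr"] = float(np.mean(splr)) >= criteria.min_splr

    duration = segment.t_ms[-1] - segment.t_ms[0] if n else 0.0
    flags["duration"] = n >= 2 and duration >= criteria.min_duration_ms

    sd_td = _sample_sd(segment.td_us)
    flags["sd_td"] = not np.isnan(sd_td) and sd_td < criteria.max_sd_td_us

    sd_spl = _sample_sd(segment.spl_a)
    if np.isnan(sd_spl):
        flags["cv_spl_a"] = False
    else:
        cv_pct = sd_spl / float(np.mean(segment.spl_a)) * 100.0
        flags["cv_spl_a"] = cv_pct <= criteria.max_cv_spl_pct

    return {name: bool(flags[name]) for name in CLICK_CRITERION_NAMES}


def detect_click_trains(
    series: PulseSeries, criteria: ClickTrainCriteria = ClickTrainCriteria()
) -> list[CandidateEvent]:
    """Run the click-train branch: clean reflections, segment, test.

    Returns *all* segments with at least two pulses, each carrying the
    nine criterion flags (indices refer to the reflection-cleaned
    series, which :func:`remove_reflections` reproduces deterministically).
    Use :func:`passed_events` for the candidates that satisfy every
    criterion.  Emitted events are disjoint in time.
    """
    cleaned = remove_reflections(series, criteria.min_pi_ms)
    events = []
    for start, stop in segment_by_gap(cleaned, criteria.max_pi_ms, "exceeds"):
        if stop - start < 2:
            continue
        segment = cleaned.slice(start, stop)
        flags = evaluate_clicktrain_criteria(segment, criteria)
        events.append(
            CandidateEvent(
                kind="clicktrain",
                start_index=int(start),
                stop_index=int(stop),
                t_start_ms=float(cleaned.t_ms[start]),
                t_end_ms=float(cleaned.t_ms[stop - 1]),
                criterion_flags=flags,
            )
        )
    return events


def detect_vessel_events(
    series: PulseSeries, criteria: VesselCriteria = VesselCriteria()
) -> list[CandidateEvent]:
    """Run the vessel branch on the raw series (no reflection removal).

    Splits at gaps >= ``max_pi_ms`` and flags each segment for pulse
    count (> ``min_pulses - 1``) and continuous duration
    (>= ``min_duration_s``).  All segments with at least two pulses are
    reported; :func:`passed_events` selects the accepted ones.
    """
    events = []
    for start, stop in segment_by_gap(series, criteria.max_pi_ms, "at_or_exceeds"):
        if stop - start < 2:
            continue
        n = stop - start
        duration_ms = series.t_ms[stop - 1] - series.t_ms[start]
        flags = {
            "max_pulse_interval": True,
            "min_pulses": n >= criteria.min_pulses,
            "duration": duration_ms >= criteria.min_duration_s * 1000.0,
        }
        events.append(
            CandidateEvent(
                kind="vessel",
                start_index=int(start),
                stop_index=int(stop),
                t_start_ms=float(series.t_ms[start]),
                t_end_ms=float(series.t_ms[stop - 1]),
                criterion_flags=flags,
            )
        )
    return events


def passed_events(events: Sequence[CandidateEvent]) -> list[CandidateEvent]:
    """Candidates satisfying every criterion of their branch."""
    return [e for e in events if e.passed]


def events_to_frame(events: Sequence[CandidateEvent]) -> pd.DataFrame:
    """Export candidates as a flat table (one column per criterion flag)."""
    if not events:
        return pd.DataFrame(
            columns=["kind", "t_start_ms", "t_end_ms", "n_pulses", "passed"]
        )
    flag_names = list(events[0].criterion_flags)
    rows = []
    for e in events:
        row = {
            "kind": e.kind,
            "t_start_ms": e.t_start_ms,
            "t_end_ms": e.t_end_ms,
            "n_pulses": e.n_pulses,
            "passed": e.passed,
        }
        row.update(e.criterion_flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=["kind", "t_start_ms", "t_end_ms", "n_pulses", "passed", *flag_names])
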