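"""Per-event feature vectors for the random-forest classifiers.

Every candidate event is summarized by order statistics of its pulse
intervals, sound-pressure ratios (hydrophone A/B), signed stereo
arrival-time differences and hydrophone-A pressures, plus pulse count,
duration and minute-truncated start/end timestamps.  The click branch
adds ``buzz_check``, a binary flag for the buzz definition (five or more
consecutive pulses with intervals <= 10 ms); the vessel branch omits it,
giving 18 and 17 features respectively.

Timestamps are encoded as minutes since the Unix epoch, truncated to
the minute: temporal features let a classifier pick up diel and
seasonal structure in animal activity.  All standard deviations are
sample SDs (n-1).  ``max_td_us`` is the maximum of the *signed*
arrival-time differences, matching the feature's definition as a signed
bearing proxy.  Column order is fixed so trained models are portable.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from pulsetrain.filters import CandidateEvent
from pulsetrain.pulse_io import PulseSeries, ensure_utc

__all__ = [
    "CLICK_FEATURE_COLUMNS",
    "VESSEL_FEATURE_COLUMNS",
    "BUZZ_MAX_INTERVAL_MS",
    "BUZZ_MIN_PULSES",
    "compute_buzz_check",
    "extract_features",
    "features_frame",
]

#: A buzz: at least this many consecutive pulses ...
BUZZ_MIN_PULSES = 5
#: ... with every inter-pulse interval at or below this (ms).
BUZZ_MAX_INTERVAL_MS = 10.0

#: Fixed, versioned feature order for the click branch (18 values).
CLICK_FEATURE_COLUMNS = (
    "np_pulses",
    "duration_ms",
    "start_epoch_min",
    "end_epoch_min",
    "max_pi_ms",
    "min_pi_ms",
    "av_pi_ms",
    "sd_pi_ms",
    "max_splr",
    "av_splr",
    "sd_splr",
    "max_td_us",
    "av_td_us",
    "sd_td_us",
    "max_spl_a",
    "av_spl_a",
    "sd_spl_a",
    "buzz_check",
)

#: Vessel branch: the same vector without ``buzz_check`` (17 values).
VESSEL_FEATURE_COLUMNS = CLICK_FEATURE_COLUMNS[:-1]


def compute_buzz_check(
    t_ms: Sequence[float] | np.ndarray,
    max_interval_ms: float = BUZZ_MAX_INTERVAL_MS,
    min_pulses: int = BUZZ_MIN_PULSES,
) -> int:
    """1 iff the pulse times contain a buzz, else 0.

    A buzz is a run of ``min_pulses`` or more consecutive pulses whose
    successive intervals are all <= ``max_interval_ms``; equivalently a
    run of ``min_pulses - 1`` qualifying intervals.
    """
    t = np.asarray(t_ms, dtype=float)
    if len(t) < min_pulses:
        return 0
    ok = np.diff(t) <= max_interval_ms
    run = 0
    for flag in ok:
        run = run + 1 if flag else 0
        if run >= min_pulses - 1:
            return 1
    return 0


def _epoch_minute(series: PulseSeries, t_ms: float) -> int:
    """Minutes since the Unix epoch of ``start_datetime + t_ms``, truncated."""
    start = ensure_utc(series.start_datetime)
    seconds = start.timestamp() + t_ms / 1000.0
    return math.floor(seconds / 60.0)


def extract_features(
    series: PulseSeries,
    event: CandidateEvent,
    branch: Literal["click", "vessel"],
) -> dict:
    """Compute the feature vector of one candidate event.

    ``series`` must be the series the event's indices refer to (the
    reflection-cleaned series for click candidates, the raw series for
    vessel candidates) and must carry ``start_datetime``.  Events with a
    single pulse cannot be featurized (interval statistics undefined).
    """
    if branch not in ("click", "vessel"):
        raise ValueError(f"unknown branch {branch!r}")
    if series.start_datetime is None:
        raise ValueError(
            "series.start_datetime is required to derive start/end timestamps"
        )
    if event.n_pulses < 2:
        raise ValueError("cannot featurize an event with fewer than 2 pulses")

    seg = series.slice(event.start_index, event.stop_index)
    pi = np.diff(seg.t_ms)
    splr = seg.spl_a / seg.spl_b

    features = {
        "np_pulses": float(len(seg)),
        "duration_ms": float(seg.t_ms[-1] - seg.t_ms[0]),
        "start_epoch_min": float(_epoch_minute(series, seg.t_ms[0])),
        "end_epoch_min": float(_epoch_minute(series, seg.t_ms[-1])),
        "max_pi_ms": float(np.max(pi)),
        "min_pi_ms": float(np.min(pi)),
        "av_pi_ms": float(np.mean(pi)),
        "sd_pi_ms": float(np.std(pi, ddof=1)) if len(pi) > 1 else 0.0,
        "max_splr": float(np.max(splr)),
        "av_splr": float(np.mean(splr)),
        "sd_splr": float(np.std(splr, ddof=1)),
        "max_td_us": float(np.max(seg.td_us)),
        "av_td_us": float(np.mean(seg.td_us)),
        "sd_td_us": float(np.std(seg.td_us, ddof=1)),
        "max_spl_a": float(np.max(seg.spl_a)),
        "av_spl_a": float(np.mean(seg.spl_a)),
        "sd_spl_a": float(np.std(seg.spl_a, ddof=1)),
    }
    if branch == "click":
        features["buzz_check"] = float(compute_buzz_check(seg.t_ms))
        return {name: features[name] for name in CLICK_FEATURE_COLUMNS}
    return {name: features[name] for name in VESSEL_FEATURE_COLUMNS}


def features_frame(
    series: PulseSeries,
    events: Sequence[CandidateEvent],
    branch: Literal["click", "vessel"],
) -> pd.DataFrame:
    """Feature matrix for a list of candidates (one row per event).

    Adds ``event_id`` (positional) and ``kind`` columns ahead of the
    fixed feature order; labels can be joined on ``event_id``.
    """
    columns = CLICK_FEATURE_COLUMNS if branch == "click" else VESSEL_FEATURE_COLUMNS
    rows = []
    for i, event in enumerate(events):
        row = {"event_id": i, "kind": event.kind}
        row.update(extract_features(series, event, branch))
        rows.append(row)
    return pd.DataFrame(rows, columns=["event_id", "kind", *columns])
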