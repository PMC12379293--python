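"""Data model and CSV interchange I/O for pulse-event streams.

A stereo pulse event recorder stores one row per detected ultrasonic
pulse: detection time (0.5 ms resolution), received sound pressure on
hydrophones A and B (linear, relative to 1 Pa), and the arrival-time
difference between the hydrophones (0.25 µs resolution, positive when
the pulse reached hydrophone A first).  Pressures are kept on a linear
scale because the downstream sound-pressure-ratio (SPLR) and
coefficient-of-variation criteria are ratios of linear quantities; dB
values are converted on ingest.

Interchange formats
-------------------
Pulse CSV (UTF-8, header mandatory)::

    t_ms,spl_a_pa,spl_b_pa,td_us

with an optional JSON sidecar (``<stem>.json``) carrying
``start_datetime`` (ISO 8601), ``threshold_db`` and free-form metadata.

Annotation CSV::

    t_start_ms,t_end_ms,label
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIME_RESOLUTION_MS",
    "TD_RESOLUTION_US",
    "DEFAULT_THRESHOLD_DB",
    "ANNOTATION_LABELS",
    "PULSE_COLUMNS",
    "ANNOTATION_COLUMNS",
    "SchemaError",
    "ValidationError",
    "PulseRecord",
    "PulseSeries",
    "AnnotationEvent",
    "db_to_linear",
    "linear_to_db",
    "read_pulses",
    "write_pulses",
    "read_annotations",
    "write_annotations",
]

#: Minimum time resolution of the recorder clock (ms).
TIME_RESOLUTION_MS = 0.5
#: Resolution of the stereo arrival-time difference (µs).
TD_RESOLUTION_US = 0.25
#: Amplitude detection threshold of the recorder (dB re 1 µPa).
DEFAULT_THRESHOLD_DB = 139.0

ANNOTATION_LABELS = frozenset(
    {"regular_click", "buzz", "click_train", "vessel", "noise"}
)

PULSE_COLUMNS = ("t_ms", "spl_a_pa", "spl_b_pa", "td_us")
ANNOTATION_COLUMNS = ("t_start_ms", "t_end_ms", "label")


class SchemaError(ValueError):
    """A file does not match the interchange schema."""


class ValidationError(ValueError):
    """Data violate a pulse-series invariant (quantization, ordering, threshold)."""


def db_to_linear(level_db: float) -> float:
    """Convert a sound pressure level in dB re 1 µPa to pressure in Pa.

    ``p = 10**(L/20) * 1e-6`` so that 120 dB re 1 µPa is exactly 1 Pa.
    """
    return 10.0 ** (level_db / 20.0) * 1e-6


def linear_to_db(pressure_pa: float) -> float:
    """Inverse of :func:`db_to_linear` (pressure in Pa to dB re 1 µPa)."""
    return 20.0 * math.log10(pressure_pa / 1e-6)


class PulseRecord(NamedTuple):
    """One detected ultrasonic pulse."""

    t_ms: float  #: detection time since recording start, multiple of 0.5 ms
    spl_a: float  #: received pressure at hydrophone A (Pa), >= threshold
    spl_b: float  #: received pressure at hydrophone B (Pa), >= threshold
    td_us: float  #: arrival-time difference A-B (µs), multiple of 0.25; >0 = A first


def _is_multiple(values: np.ndarray, step: float) -> np.ndarray:
    scaled = values / step
    return scaled == np.round(scaled)


@dataclass
class PulseSeries:
    """Time-ordered pulse stream plus recording metadata.

    Internally column-oriented (one numpy array per field) because the
    rule-based filters are vectorized sweeps over intervals and ratios.
    """

    t_ms: np.ndarray
    spl_a: np.ndarray
    spl_b: np.ndarray
    td_us: np.ndarray
    start_datetime: datetime | None = None
    threshold_db: float = DEFAULT_THRESHOLD_DB
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.spl_a = np.asarray(self.spl_a, dtype=float)
        self.spl_b = np.asarray(self.spl_b, dtype=float)
        self.td_us = np.asarray(self.td_us, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        n = len(self.t_ms)
        if not (len(self.spl_a) == len(self.spl_b) == len(self.td_us) == n):
            raise ValidationError("pulse field arrays have unequal lengths")
        if n == 0:
            return
        bad = np.flatnonzero(~_is_multiple(self.t_ms, TIME_RESOLUTION_MS))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: t_ms={self.t_ms[bad[0]]} is not a multiple of "
                f"{TIME_RESOLUTION_MS} ms"
            )
        bad = np.flatnonzero(~_is_multiple(self.td_us, TD_RESOLUTION_US))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: td_us={self.td_us[bad[0]]} is not a multiple of "
                f"{TD_RESOLUTION_US} µs"
            )
        if n > 1:
            diffs = np.diff(self.t_ms)
            bad = np.flatnonzero(diffs <= 0)
            if bad.size:
                i = bad[0] + 1
                raise ValidationError(
                    f"row {i}: t_ms={self.t_ms[i]} does not strictly increase "
                    f"(previous row has t_ms={self.t_ms[i - 1]})"
                )
        thr = db_to_linear(self.threshold_db) * (1.0 - 1e-12)
        for name, arr in (("spl_a", self.spl_a), ("spl_b", self.spl_b)):
            bad = np.flatnonzero(~(arr >= thr))
            if bad.size:
                raise ValidationError(
                    f"row {bad[0]}: {name}={arr[bad[0]]} Pa is below the "
                    f"detection threshold ({self.threshold_db} dB re 1 µPa)"
                )

    # -- container protocol --------------------------------------------
    def __len__(self) -> int:
        return len(self.t_ms)

    def __iter__(self) -> Iterator[PulseRecord]:
        return iter(self.records)

    @property
    def records(self) -> list[PulseRecord]:
        return [
            PulseRecord(*row)
            for row in zip(self.t_ms, self.spl_a, self.spl_b, self.td_us)
        ]

    def slice(self, start: int, stop: int) -> "PulseSeries":
        """Contiguous sub-series [start, stop) sharing the metadata."""
        return PulseSeries(
            self.t_ms[start:stop],
            self.spl_a[start:stop],
            self.spl_b[start:stop],
            self.td_us[start:stop],
            start_datetime=self.start_datetime,
            threshold_db=self.threshold_db,
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "spl_a_pa": self.spl_a,
                "spl_b_pa": self.spl_b,
                "td_us": self.td_us,
            }
        )

    @classmethod
    def from_records(
        cls, records: Sequence[PulseRecord | tuple], **kwargs
    ) -> "PulseSeries":
        if len(records) == 0:
            empty = np.empty(0)
            return cls(empty, empty, empty, empty, **kwargs)
        arr = np.asarray(records, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], **kwargs)


@dataclass(frozen=True)
class AnnotationEvent:
    """Manually (or synthetically) annotated event span in series time."""

    t_start_ms: float
    t_end_ms: float
    label: str

    def __post_init__(self) -> None:
        if self.t_start_ms > self.t_end_ms:
            raise ValidationError(
                f"annotation start {self.t_start_ms} after end {self.t_end_ms}"
            )
        if self.label not in ANNOTATION_LABELS:
            raise ValidationError(
                f"unknown annotation label {self.label!r}; "
                f"expected one of {sorted(ANNOTATION_LABELS)}"
            )


# ---------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------


def _check_header(frame: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_pulses(path: str | Path, sidecar: str | Path | None = None) -> PulseSeries:
    """Read a pulse CSV (plus optional JSON sidecar) into a validated series.

    Rows violating quantization, ordering or the detection threshold are
    reported via :class:`ValidationError` naming the first offending row;
    nothing is silently fixed.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_header(frame, PULSE_COLUMNS, path)

    start_datetime = None
    threshold_db = DEFAULT_THRESHOLD_DB
    meta: dict = {}
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        if "start_datetime" in payload:
            start_datetime = datetime.fromisoformat(payload.pop("start_datetime"))
        threshold_db = float(payload.pop("threshold_db", DEFAULT_THRESHOLD_DB))
        meta = payload

    return PulseSeries(
        frame["t_ms"].to_numpy(float),
        frame["spl_a_pa"].to_numpy(float),
        frame["spl_b_pa"].to_numpy(float),
        frame["td_us"].to_numpy(float),
        start_datetime=start_datetime,
        threshold_db=threshold_db,
        meta=meta,
    )


def write_pulses(series: PulseSeries, path: str | Path) -> None:
    """Write a series to the pulse CSV format (and sidecar when metadata exist).

    ``read_pulses(write_pulses(s))`` reproduces every field exactly:
    floats are serialized with ``repr`` round-trip precision.
    """
    path = Path(path)
    # %.17g guarantees binary round-trip of every IEEE double
    series.to_frame().to_csv(path, index=False, float_format="%.17g")
    if series.start_datetime is not None or series.meta or (
        series.threshold_db != DEFAULT_THRESHOLD_DB
    ):
        payload = dict(series.meta)
        payload["threshold_db"] = series.threshold_db
        if series.start_datetime is not None:
            payload["start_datetime"] = series.start_datetime.isoformat()
        _sidecar_path(path).write_text(json.dumps(payload, indent=2))


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    path = Path(path)
    frame = pd.read_csv(path)
    _check_header(frame, ANNOTATION_COLUMNS, path)
    return [
        AnnotationEvent(float(r.t_start_ms), float(r.t_end_ms), str(r.label))
        for r in frame.itertuples(index=False)
    ]


def write_annotations(events: Sequence[AnnotationEvent], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.t_start_ms, e.t_end_ms, e.label) for e in events],
        columns=list(ANNOTATION_COLUMNS),
    )
    frame.to_csv(path, index=False)


def ensure_utc(dt: datetime) -> datetime:
    """Interpret naive datetimes as UTC so epoch arithmetic is unambiguous."""
    if dt.tzinfo is None:
        return dt.replace(tzinfo=timezone.utc)
    return dt
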