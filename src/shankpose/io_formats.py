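"""Readers and writers for the plain-text artifacts of the pipeline.

All on-disk formats are comma-separated tables with a header row:

* event stream:   ``start_s,duration_s,code``
* raw recording:  ``x,y,z`` (optional leading ``t`` column, ignored on read)
* feature matrix: one column per named feature plus ``label``,
  ``window_start_s``, ``window_length_s`` and optionally ``subject_id``

Times are seconds relative to the recording origin; accelerations are in
units of g.  Vendor binary exports are out of scope: processing starts
after export to these tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The posture taxonomy emitted by a thigh-worn event-based activity monitor.
POSTURE_CODES = (
    "sitting",
    "standing",
    "stepping",
    "cycling",
    "primary_lying",
    "secondary_lying",
    "non_wear",
    "travelling",
)

#: Metadata columns a feature matrix carries next to its feature columns.
META_COLUMNS = ("label", "window_start_s", "window_length_s", "subject_id")


class FormatError(ValueError):
    """A file does not have the expected tabular layout."""


class ValidationError(ValueError):
    """A file parsed fine but violates a domain invariant."""


@dataclass(frozen=True)
class PostureEvent:
    """One labelled interval: ``[start, start + duration)`` seconds."""

    start: float
    duration: float
    code: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(f"event duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class PostureEventStream:
    """An ordered, non-overlapping sequence of posture events."""

    events: tuple[PostureEvent, ...]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.start < prev.start:
                raise ValidationError(
                    f"events out of order: event at {cur.start} s follows "
                    f"event at {prev.start} s"
                )
            if cur.start < prev.end - 1e-9:
                raise ValidationError(
                    f"overlapping events: [{prev.start}, {prev.end}) s and "
                    f"[{cur.start}, {cur.end}) s"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def span(self) -> float:
        """End time of the last event (0 for an empty stream)."""
        return self.events[-1].end if self.events else 0.0


@dataclass(frozen=True)
class RawRecording:
    """A uniformly sampled tri-axial acceleration trace in g."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = 20.0
    start_time: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        n = len(self.x)
        if not (len(self.y) == len(self.z) == n):
            raise ValidationError(
                f"axes have ragged lengths: x={len(self.x)}, y={len(self.y)}, "
                f"z={len(self.z)}"
            )
        if n < 1:
            raise ValidationError("recording must contain at least one sample")
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(axis)):
                raise ValidationError(f"non-finite value in axis {name!r}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (samples / sample_rate)."""
        return len(self) / self.sample_rate


def read_events(path) -> PostureEventStream:
    """Read a ``start_s,duration_s,code`` table into a validated stream.

    Unknown posture codes, negative durations and overlapping events are
    rejected; an empty table (header only) yields an empty stream.
    """
    df = pd.read_csv(path)
    required = {"start_s", "duration_s", "code"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        code = str(row.code)
        if code not in POSTURE_CODES:
            raise ValidationError(
                f"{path}: unknown posture code {code!r}; expected one of "
                f"{POSTURE_CODES}"
            )
        events.append(PostureEvent(float(row.start_s), float(row.duration_s), code))
    return PostureEventStream(tuple(events))


def write_events(stream: PostureEventStream, path) -> None:
    df = pd.DataFrame(
        {
            "start_s": [e.start for e in stream],
            "duration_s": [e.duration for e in stream],
            "code": [e.code for e in stream],
        }
    )
    df.to_csv(path, index=False)


def read_raw(path, sample_rate: float = 20.0, subject_id: str = "") -> RawRecording:
    """Read an ``x,y,z`` acceleration table sampled at ``sample_rate`` Hz."""
    df = pd.read_csv(path)
    required = {"x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            raise ValidationError(f"{path}: non-finite or non-numeric {col!r} at row {bad}")
    return RawRecording(
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        sample_rate=sample_rate,
        subject_id=subject_id,
    )


def write_raw(recording: RawRecording, path, float_format: str | None = "%.5f") -> None:
    df = pd.DataFrame({"x": recording.x, "y": recording.y, "z": recording.z})
    df.to_csv(path, index=False, float_format=float_format)


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix (features + metadata columns) to CSV.

    Column names must be unique and a ``label`` column must be present.
    """
    if matrix.columns.duplicated().any():
        dupes = sorted(set(matrix.columns[matrix.columns.duplicated()]))
        raise ValidationError(f"duplicated column name(s): {dupes}")
    if "label" not in matrix.columns:
        raise ValidationError("feature matrix must carry a 'label' column")
    matrix.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"{path}: duplicated column name(s): {dupes}")
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing 'label' column")
    return df


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything that is not metadata)."""
    return [c for c in matrix.columns if c not in META_COLUMNS]
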