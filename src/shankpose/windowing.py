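"""Event-stream merging and fixed-length overlapped window extraction.

The thigh monitor's eight posture codes are merged down to the four
behaviour classes used for modelling (sitting, standing, stepping,
lying); non-wear and travelling intervals are discarded.  The raw shank
signal is then cut into fixed-length windows sliding on a grid anchored
at the recording origin with 50% overlap by default, and a window is
kept only if it lies entirely inside a single merged event — windows
spanning a posture transition are dropped so that every training sample
carries an unambiguous label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    PostureEvent,
    PostureEventStream,
    RawRecording,
    ValidationError,
)

#: The four merged behaviour classes.
MERGED_LABELS = ("sitting", "standing", "stepping", "lying")

#: Window lengths (seconds) swept by default.
DEFAULT_WINDOW_LENGTHS = (5.0, 15.0, 30.0, 60.0, 120.0, 180.0)

_MERGE_MAP = {
    "sitting": "sitting",
    "standing": "standing",
    "stepping": "stepping",
    "cycling": "stepping",
    "primary_lying": "lying",
    "secondary_lying": "lying",
    "lying": "lying",  # idempotence on already-merged streams
}
_DROP_CODES = {"non_wear", "travelling"}

_TOL = 1e-9


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-duration slice of the signal carrying one merged label."""

    start: float
    length: float
    label: str
    samples: np.ndarray  # shape (n, 3) columns x, y, z, in g
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in MERGED_LABELS:
            raise ValidationError(f"unknown merged label {self.label!r}")


@dataclass
class WindowedDataset:
    """All same-length windows extracted from one or more recordings."""

    window_length: float
    overlap_fraction: float
    windows: list[LabeledWindow] = field(default_factory=list)
    sample_rate: float = 20.0
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.windows:
            counts[w.label] = counts.get(w.label, 0) + 1
        return counts

    def extend(self, other: "WindowedDataset") -> None:
        """Append another dataset's windows (same length/rate required)."""
        if other.window_length != self.window_length:
            raise ValidationError("cannot merge datasets of different window lengths")
        if other.sample_rate != self.sample_rate:
            raise ValidationError("cannot merge datasets of different sample rates")
        self.windows.extend(other.windows)
        self.provenance.extend(other.provenance)


def merge_labels(stream: PostureEventStream) -> PostureEventStream:
    """Collapse the eight posture codes to the four modelling classes.

    Cycling becomes stepping; primary and secondary lying become lying;
    non-wear and travelling events are deleted.  Adjacent events that end
    up with the same label are coalesced, since purity of a window is a
    property of the label, not of event identity.
    """
    merged: list[PostureEvent] = []
    for ev in stream:
        if ev.code in _DROP_CODES:
            continue
        label = _MERGE_MAP[ev.code]
        if (
            merged
            and merged[-1].code == label
            and abs(merged[-1].end - ev.start) <= _TOL
        ):
            prev = merged.pop()
            merged.append(PostureEvent(prev.start, prev.duration + ev.duration, label))
        else:
            merged.append(PostureEvent(ev.start, ev.duration, label))
    return PostureEventStream(tuple(merged))


def extract_windows(
    recording: RawRecording,
    merged_stream: PostureEventStream,
    window_length_s: float,
    overlap_fraction: float = 0.5,
) -> WindowedDataset:
    """Slice the recording into pure, fixed-length, overlapped windows.

    Candidate windows start at the recording origin and advance by
    ``window_length_s * (1 - overlap_fraction)``; a candidate is kept iff
    its full interval lies inside a single merged event, and it then
    carries that event's label together with a copy of its samples.
    """
    if window_length_s <= 0:
        raise ValidationError(f"window length must be > 0, got {window_length_s}")
    if not (0 <= overlap_fraction < 1):
        raise ValidationError(
            f"overlap fraction must be in [0, 1), got {overlap_fraction}"
        )
    # recordings are quantized to the sample grid: allow up to one sample slack
    if merged_stream.span > recording.duration + 1.0 / recording.sample_rate:
        raise ValidationError(
            f"event stream extends to {merged_stream.span} s but the recording "
            f"covers only {recording.duration} s"
        )
    for ev in merged_stream:
        if ev.code not in MERGED_LABELS:
            raise ValidationError(
                f"stream contains unmerged code {ev.code!r}; run merge_labels first"
            )

    fs = recording.sample_rate
    step = window_length_s * (1.0 - overlap_fraction)
    n_win = int(round(window_length_s * fs))
    dataset = WindowedDataset(
        window_length=window_length_s,
        overlap_fraction=overlap_fraction,
        sample_rate=fs,
        provenance=[recording.subject_id] if recording.subject_id else [],
    )
    duration = recording.duration
    if window_length_s > duration + _TOL:
        return dataset

    xyz = np.column_stack([recording.x, recording.y, recording.z])
    events = list(merged_stream)
    ei = 0  # events and candidates both advance monotonically
    i = 0
    while True:
        start = i * step
        if start + window_length_s > duration + _TOL:
            break
        i += 1
        while ei < len(events) and events[ei].end < start + window_length_s - _TOL:
            ei += 1
        if ei >= len(events):
            break
        ev = events[ei]
        if ev.start <= start + _TOL and start + window_length_s <= ev.end + _TOL:
            i0 = int(round(start * fs))
            dataset.windows.append(
                LabeledWindow(
                    start=start,
                    length=window_length_s,
                    label=ev.code,
                    samples=xyz[i0 : i0 + n_win].copy(),
                    subject_id=recording.subject_id,
                )
            )
    return dataset


def sweep_window_lengths(
    recording: RawRecording,
    merged_stream: PostureEventStream,
    lengths=DEFAULT_WINDOW_LENGTHS,
    overlap_fraction: float = 0.5,
) -> list[WindowedDataset]:
    """Extract one independent windowed dataset per requested length."""
    return [
        extract_windows(recording, merged_stream, float(L), overlap_fraction)
        for L in lengths
    ]


def truncate_days(
    stream: PostureEventStream, recording: RawRecording, n_days: float = 3
) -> tuple[PostureEventStream, RawRecording]:
    """Clip both inputs to the first ``n_days`` so subjects contribute equally.

    An event straddling the cut is truncated at the boundary; a recording
    shorter than the cut is returned unchanged.
    """
    cut = n_days * 86400.0
    events = []
    for ev in stream:
        if ev.start >= cut:
            continue
        if ev.end > cut:
            events.append(PostureEvent(ev.start, cut - ev.start, ev.code))
        else:
            events.append(ev)
    n_keep = int(round(cut * recording.sample_rate))
    if n_keep < len(recording):
        recording = RawRecording(
            x=recording.x[:n_keep],
            y=recording.y[:n_keep],
            z=recording.z[:n_keep],
            sample_rate=recording.sample_rate,
            start_time=recording.start_time,
            subject_id=recording.subject_id,
        )
    return PostureEventStream(tuple(events)), recording
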