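"""Reading, writing and segmenting annotated song timestamps.

The unit of all downstream rhythm analysis is the *song chunk*: a run of
continuously sung notes in which no internal silent gap reaches 300 ms.
Annotations arrive as label tracks — one row per note with onset time,
offset time and a note label — either in the tab-separated Audacity label
track dialect (``start<TAB>end<TAB>label``, seconds) or as a CSV with the
header ``onset,offset,label``.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NoteEvent",
    "SongChunk",
    "DurationTable",
    "LabelParseError",
    "parse_label_file",
    "write_label_file",
    "segment_chunks",
    "filter_chunks",
    "build_duration_table",
    "chunk_manifest",
    "DEFAULT_PAUSE_THRESHOLD",
    "DEFAULT_EXCLUDE_LABELS",
]

#: Silent pause (s) at or above which a new chunk starts.
DEFAULT_PAUSE_THRESHOLD = 0.300

#: Labels treated as introductory notes / calls and dropped before chunking.
DEFAULT_EXCLUDE_LABELS = frozenset({"i", "call"})


class LabelParseError(ValueError):
    """Raised when a label file row cannot be parsed or validated."""


@dataclass(frozen=True)
class NoteEvent:
    """A single annotated note: onset and offset in seconds, plus a label."""

    onset: float
    offset: float
    label: str

    def __post_init__(self) -> None:
        if not (self.onset < self.offset):
            raise ValueError(
                f"note onset must precede offset (got onset={self.onset}, "
                f"offset={self.offset}, label={self.label!r})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SongChunk:
    """An ordered run of notes with no internal silence >= the pause threshold."""

    bird_id: str
    chunk_index: int
    events: list[NoteEvent]
    context: str = "undirected"

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset < prev.offset:
                raise ValueError(
                    f"overlapping notes in chunk {self.bird_id}/{self.chunk_index}: "
                    f"{prev!r} followed by {nxt!r}"
                )

    @property
    def n_notes(self) -> int:
        return len(self.events)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.events], dtype=float)

    @property
    def iois(self) -> np.ndarray:
        """Inter-onset intervals; one fewer than the number of notes."""
        return np.diff(self.onsets)

    @property
    def gaps(self) -> np.ndarray:
        """Silent intervals between consecutive notes (may contain zeros)."""
        ons = self.onsets
        offs = self.offsets
        return ons[1:] - offs[:-1]

    @property
    def start(self) -> float:
        return self.events[0].onset

    @property
    def end(self) -> float:
        return self.events[-1].offset

    @property
    def ref(self) -> tuple[str, int]:
        return (self.bird_id, self.chunk_index)


@dataclass
class DurationTable:
    """Per-type duration samples: notes keyed by label, gaps by preceding note.

    The gap following note ``a`` is keyed ``"a"`` here and rendered ``a'``
    in human-facing output; gaps are associated with the preceding note
    because note duration covaries more with the following gap.
    """

    note_durations: dict[str, list[float]] = field(default_factory=dict)
    gap_durations: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_notes(self) -> int:
        return sum(len(v) for v in self.note_durations.values())

    @property
    def n_gaps(self) -> int:
        return sum(len(v) for v in self.gap_durations.values())

    def pooled_notes(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.note_durations.values()]) \
            if self.note_durations else np.empty(0)

    def pooled_gaps(self) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in self.gap_durations.values()]) \
            if self.gap_durations else np.empty(0)


def _parse_time(token: str, lineno: int, path: str) -> float:
    try:
        value = float(token)
    except ValueError as exc:
        raise LabelParseError(
            f"{path}:{lineno}: cannot parse time field {token!r}"
        ) from exc
    if value < 0 or not np.isfinite(value):
        raise LabelParseError(f"{path}:{lineno}: negative or non-finite time {token!r}")
    return value


def parse_label_file(path: str | Path, dialect: str = "audacity_tsv") -> list[NoteEvent]:
    """Read a label track into a sorted list of :class:`NoteEvent`.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"audacity_tsv"`` for the header-less tab-separated Audacity label
        track, ``"csv"`` for a CSV with header ``onset,offset,label``.

    Raises
    ------
    LabelParseError
        On malformed rows or onset >= offset, naming the offending line.
    """
    path = Path(path)
    if dialect not in ("audacity_tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    events: list[NoteEvent] = []
    with open(path, newline="") as fh:
        if dialect == "audacity_tsv":
            rows = csv.reader(fh, delimiter="\t")
            start_line = 1
        else:
            rows = csv.reader(fh)
            header = next(rows, None)
            if header is not None and [h.strip().lower() for h in header[:3]] != [
                "onset",
                "offset",
                "label",
            ]:
                raise LabelParseError(
                    f"{path}:1: expected CSV header 'onset,offset,label', got {header!r}"
                )
            start_line = 2
        for lineno, row in enumerate(rows, start=start_line):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise LabelParseError(
                    f"{path}:{lineno}: expected at least 3 fields, got {len(row)}"
                )
            onset = _parse_time(row[0], lineno, str(path))
            offset = _parse_time(row[1], lineno, str(path))
            label = row[2].strip()
            if onset >= offset:
                raise LabelParseError(
                    f"{path}:{lineno}: onset {onset} must precede offset {offset}"
                )
            events.append(NoteEvent(onset=onset, offset=offset, label=label))
    events.sort(key=lambda e: e.onset)
    return events


def write_label_file(
    events: Iterable[NoteEvent], path: str | Path, dialect: str = "audacity_tsv"
) -> None:
    """Write events to a label track with millisecond precision."""
    path = Path(path)
    events = sorted(events, key=lambda e: e.onset)
    with open(path, "w", newline="") as fh:
        if dialect == "audacity_tsv":
            for e in events:
                fh.write(f"{e.onset:.3f}\t{e.offset:.3f}\t{e.label}\n")
        elif dialect == "csv":
            fh.write("onset,offset,label\n")
            for e in events:
                fh.write(f"{e.onset:.3f},{e.offset:.3f},{e.label}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def segment_chunks(
    events: Sequence[NoteEvent],
    pause_threshold: float = DEFAULT_PAUSE_THRESHOLD,
    exclude_labels: Iterable[str] = DEFAULT_EXCLUDE_LABELS,
    bird_id: str = "unknown",
    context: str = "undirected",
) -> list[SongChunk]:
    """Split a sorted event stream into song chunks.

    Events whose label is in ``exclude_labels`` (introductory notes, calls)
    are removed first. A new chunk begins whenever the silent gap between
    the previous offset and the next onset is >= ``pause_threshold``
    (inclusive: a pause of exactly 300 ms separates chunks).
    """
    if pause_threshold <= 0:
        raise ValueError("pause_threshold must be positive")
    exclude = set(exclude_labels)
    kept = [e for e in events if e.label not in exclude]
    chunks: list[SongChunk] = []
    current: list[NoteEvent] = []
    for e in kept:
        if current and e.onset - current[-1].offset >= pause_threshold:
            chunks.append(SongChunk(bird_id, len(chunks), current, context))
            current = []
        current.append(e)
    if current:
        chunks.append(SongChunk(bird_id, len(chunks), current, context))
    return chunks


def filter_chunks(
    chunks: Iterable[SongChunk], min_notes: int = 4, min_distinct: int = 3
) -> list[SongChunk]:
    """Discard chunks too short or too repetitive to support a pulse fit.

    Chunks with fewer than ``min_notes`` notes (e.g. *abc*) or fewer than
    ``min_distinct`` distinct labels (e.g. *ababab*) are removed: a regular
    pulse fitted to very few or very repetitive onsets is a mathematical
    artifact rather than evidence of rhythm.
    """
    return [
        c
        for c in chunks
        if c.n_notes >= min_notes and len(set(c.labels)) >= min_distinct
    ]


def build_duration_table(chunks: Iterable[SongChunk]) -> DurationTable:
    """Pool note and gap durations per type across chunks.

    Gaps are keyed by the label of the note they follow. The silence after a
    chunk's final note is not a gap. Zero-length gaps (offset touching the
    next onset) are excluded with a warning: a gap duration must be > 0.
    """
    table = DurationTable()
    n_zero = 0
    for chunk in chunks:
        for e in chunk.events:
            table.note_durations.setdefault(e.label, []).append(e.duration)
        for prev, nxt in zip(chunk.events, chunk.events[1:]):
            gap = nxt.onset - prev.offset
            if gap <= 0:
                n_zero += 1
                continue
            table.gap_durations.setdefault(prev.label, []).append(gap)
    if n_zero:
        warnings.warn(
            f"excluded {n_zero} zero-length gap(s) from the duration table",
            stacklevel=2,
        )
    return table


def chunk_manifest(chunks: Iterable[SongChunk]) -> pd.DataFrame:
    """Tabulate chunks: bird, index, size, distinct labels, time span."""
    rows = [
        {
            "bird_id": c.bird_id,
            "chunk_index": c.chunk_index,
            "n_notes": c.n_notes,
            "n_distinct": len(set(c.labels)),
            "start": c.start,
            "end": c.end,
        }
        for c in chunks
    ]
    return pd.DataFrame(
        rows, columns=["bird_id", "chunk_index", "n_notes", "n_distinct", "start", "end"]
    )
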