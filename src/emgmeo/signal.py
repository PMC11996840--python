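"""Core containers: uniformly sampled signals and alternating change-point sets.

A :class:`Signal` is a single-channel, uniformly sampled EMG trace.  A
:class:`ChangePointSet` is the common currency between detectors, the
synthetic generator (ground truth) and the evaluation machinery: an ordered,
strictly alternating sequence of muscle-activity onset and offset events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

ONSET = "onset"
OFFSET = "offset"


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in signal units, shape ``(n,)`` with ``n >= 3``.
    fs : float
        Sampling rate in Hz, ``> 0``.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if samples.size < 3:
            raise ValueError(f"signal needs at least 3 samples, got {samples.size}")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def scaled(self, c: float) -> "Signal":
        """Return a copy with every sample multiplied by ``c``."""
        return Signal(self.samples * c, self.fs)


def ms_to_samples(ms: float, fs: float) -> int:
    """Convert a duration in milliseconds to a sample count: round(ms*fs/1000).

    Single conversion point used by every stage so that millisecond-denominated
    physiological parameters stay decoupled from the sampling rate.
    """
    return int(round(ms * fs / 1000.0))


@dataclass(frozen=True)
class ChangePoint:
    """One detected or true event: an activity onset or offset."""

    kind: str  # ONSET or OFFSET
    time: float  # seconds
    index: int  # 0-based sample index

    def __post_init__(self) -> None:
        if self.kind not in (ONSET, OFFSET):
            raise ValueError(f"event kind must be 'onset' or 'offset', got {self.kind!r}")


@dataclass(frozen=True)
class ChangePointSet:
    """Ordered, strictly alternating onset/offset events.

    Invariants enforced on construction: times strictly increase, kinds
    alternate starting with an onset, and every onset precedes its paired
    offset.  An empty set is valid (nothing detected).
    """

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(self.events)
        for i, ev in enumerate(events):
            expected = ONSET if i % 2 == 0 else OFFSET
            if ev.kind != expected:
                raise ValueError(
                    f"event {i} must be {expected!r} (alternation starting with onset), "
                    f"got {ev.kind!r}"
                )
            if i > 0 and not ev.time > events[i - 1].time:
                raise ValueError(
                    f"event times must strictly increase: "
                    f"{events[i - 1].time} !< {ev.time} at position {i}"
                )
        object.__setattr__(self, "events", events)

    @classmethod
    def from_samples(cls, kinds: Sequence[str], indices: Sequence[int], fs: float) -> "ChangePointSet":
        return cls(tuple(ChangePoint(k, i / fs, int(i)) for k, i in zip(kinds, indices)))

    @classmethod
    def from_times(cls, kinds: Sequence[str], times: Sequence[float], fs: float) -> "ChangePointSet":
        return cls(tuple(ChangePoint(k, float(t), int(round(t * fs))) for k, t in zip(kinds, times)))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple], fs: float) -> "ChangePointSet":
        """Build from (onset_time, offset_time) pairs in seconds."""
        events = []
        for on, off in pairs:
            events.append(ChangePoint(ONSET, float(on), int(round(on * fs))))
            events.append(ChangePoint(OFFSET, float(off), int(round(off * fs))))
        return cls(tuple(events))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[ChangePoint]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChangePointSet):
            return NotImplemented
        return self.events == other.events

    @property
    def onsets(self) -> np.ndarray:
        """Onset times in seconds."""
        return np.array([e.time for e in self.events[0::2]])

    @property
    def offsets(self) -> np.ndarray:
        """Offset times in seconds."""
        return np.array([e.time for e in self.events[1::2]])

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    def pairs(self) -> list:
        """(onset, offset) event pairs; requires an even event count."""
        if len(self.events) % 2:
            raise ValueError("unpaired trailing onset")
        return [(self.events[i], self.events[i + 1]) for i in range(0, len(self.events), 2)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event": [e.kind for e in self.events],
                "time_s": [e.time for e in self.events],
                "sample": [e.index for e in self.events],
            }
        )
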