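"""Region-based scoring of detected change-points against ground truth.

Detected and true change-points almost never coincide sample-for-sample, so
scoring is region-based.  Around every true change-point a *valid detection
interval* is placed — 300 ms before to 200 ms after, motivated by the
electromechanical delay of voluntary contraction (activity can lead movement
by up to ~260 ms) and the largest system latency still imperceptible to a
user (~200 ms).  These intervals partition the recording into four region
kinds:

* ``baseline``  — rest, outside every interval and activity,
* ``onset_segment``  — the valid interval around a true onset,
* ``activity``  — inside a contraction, between its two intervals,
* ``offset_segment`` — the valid interval around a true offset.

Events are then classified region by region (the revised confusion matrix):
an onset segment containing exactly one detected onset scores a TP; an empty
one an FN; one containing multiple events or a wrong-kind event scores an FP
(and no TP).  Offset segments are scored symmetrically.  Empty baseline and
activity regions each contribute one TN; every stray event in them is an FP.
Metrics follow: per-kind TPR = TP/N_true, pooled F1 = 2TP/(2TP+FN+FP)·100,
and per-kind timing bias = root-mean-square deviation (ms) over the matched
TP pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .signal import OFFSET, ONSET, ChangePointSet

BASELINE = "baseline"
ONSET_SEGMENT = "onset_segment"
ACTIVITY = "activity"
OFFSET_SEGMENT = "offset_segment"


@dataclass(frozen=True)
class Region:
    kind: str
    start: float
    end: float
    event_time: Optional[float] = None  # associated true change-point, if any

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RegionPartition:
    """Ordered regions tiling [0, duration] without overlap."""

    regions: tuple
    duration: float

    def __post_init__(self) -> None:
        regs = tuple(self.regions)
        t = 0.0
        for r in regs:
            if not np.isclose(r.start, t):
                raise ValueError(f"regions do not tile: gap/overlap at {r.start} (expected {t})")
            if r.end < r.start:
                raise ValueError(f"region {r} has negative length")
            t = r.end
        if regs and not np.isclose(t, self.duration):
            raise ValueError(f"regions end at {t}, recording lasts {self.duration}")
        object.__setattr__(self, "regions", regs)


def build_regions(
    truth: ChangePointSet,
    duration: float,
    pre_ms: float = 300.0,
    post_ms: float = 200.0,
) -> RegionPartition:
    """Partition [0, duration] into the four region kinds.

    Each true change-point t gets the valid interval [t − pre, t + post],
    clipped to the recording.  Within one contraction, if the onset interval
    would overrun the offset interval (contractions shorter than pre+post),
    the two are split at the midpoint of the overlap so they abut and the
    activity region is empty.  Valid intervals of *different* contractions
    (or an offset interval overrunning the next onset interval) are refused:
    such truth sets cannot be scored unambiguously.
    """
    pre = pre_ms / 1000.0
    post = post_ms / 1000.0
    if not len(truth):
        return RegionPartition((Region(BASELINE, 0.0, duration),), duration)
    if len(truth) % 2:
        raise ValueError("truth must contain complete onset/offset pairs")

    regions: list = []
    cursor = 0.0
    for on_ev, off_ev in truth.pairs():
        on, off = on_ev.time, off_ev.time
        if off > duration or on < 0:
            raise ValueError(f"truth event pair ({on}, {off}) outside the recording")
        on_start, on_end = max(0.0, on - pre), min(duration, on + post)
        off_start, off_end = max(0.0, off - pre), min(duration, off + post)
        if on_end > off_start:
            # short contraction: abut the two segments at the overlap midpoint
            mid = 0.5 * (on_end + off_start)
            if mid <= on_start or mid >= off_end:
                raise ValueError(f"contraction ({on}, {off}) too short to partition")
            on_end = off_start = mid
        if on_start < cursor - 1e-12:
            raise ValueError(
                "valid detection intervals of consecutive contractions overlap "
                f"(onset interval of t={on} starts before {cursor}); "
                "increase the spacing of the truth set"
            )
        if on_start > cursor:
            regions.append(Region(BASELINE, cursor, on_start))
        regions.append(Region(ONSET_SEGMENT, on_start, on_end, on))
        if off_start > on_end:
            regions.append(Region(ACTIVITY, on_end, off_start))
        regions.append(Region(OFFSET_SEGMENT, off_start, off_end, off))
        cursor = off_end
    if cursor < duration:
        regions.append(Region(BASELINE, cursor, duration))
    return RegionPartition(tuple(regions), duration)


@dataclass
class ConfusionCounts:
    """Region-classified TP/TN/FP/FN, split by event kind and pooled.

    TN is a region-level count (one per empty baseline or activity region)
    and is tracked pooled only; TP/FN/FP are per kind, the pooled values
    being their sums.
    """

    tp: dict = field(default_factory=lambda: {ONSET: 0, OFFSET: 0})
    fn: dict = field(default_factory=lambda: {ONSET: 0, OFFSET: 0})
    fp: dict = field(default_factory=lambda: {ONSET: 0, OFFSET: 0})
    tn: int = 0
    n_true: dict = field(default_factory=lambda: {ONSET: 0, OFFSET: 0})
    n_detected: dict = field(default_factory=lambda: {ONSET: 0, OFFSET: 0})

    @property
    def tp_total(self) -> int:
        return sum(self.tp.values())

    @property
    def fn_total(self) -> int:
        return sum(self.fn.values())

    @property
    def fp_total(self) -> int:
        return sum(self.fp.values())

    def add(self, other: "ConfusionCounts") -> None:
        for kind in (ONSET, OFFSET):
            self.tp[kind] += other.tp[kind]
            self.fn[kind] += other.fn[kind]
            self.fp[kind] += other.fp[kind]
            self.n_true[kind] += other.n_true[kind]
            self.n_detected[kind] += other.n_detected[kind]
        self.tn += other.tn


_SEGMENT_KIND = {ONSET_SEGMENT: ONSET, OFFSET_SEGMENT: OFFSET}


def classify_events(detected: ChangePointSet, partition: RegionPartition):
    """Apply the revised confusion matrix.

    Returns ``(counts, pairs)`` where ``pairs`` is the list of matched
    ``(kind, true_time, detected_time)`` triples of the TP events, used for
    the timing-bias metric.  Detected events outside the recording span are
    rejected with a warning and ignored.
    """
    counts = ConfusionCounts()
    duration = partition.duration
    events = []
    for ev in detected:
        if 0.0 <= ev.time <= duration:
            events.append(ev)
        else:
            warnings.warn(
                f"detected {ev.kind} at {ev.time:.3f} s outside the recording "
                f"span [0, {duration:.3f}]; ignored",
                stacklevel=2,
            )
    for ev in events:
        counts.n_detected[ev.kind] += 1

    times = np.array([ev.time for ev in events])
    pairs: list = []
    last = len(partition.regions) - 1
    for idx, region in enumerate(partition.regions):
        if idx == last:
            inside = [ev for ev, t in zip(events, times) if region.start <= t <= region.end]
        else:
            inside = [ev for ev, t in zip(events, times) if region.start <= t < region.end]
        seg_kind = _SEGMENT_KIND.get(region.kind)
        if seg_kind is None:  # baseline or activity
            if not inside:
                counts.tn += 1
            else:
                for ev in inside:
                    counts.fp[ev.kind] += 1
            continue
        counts.n_true[seg_kind] += 1
        if not inside:
            counts.fn[seg_kind] += 1
        elif len(inside) == 1 and inside[0].kind == seg_kind:
            counts.tp[seg_kind] += 1
            pairs.append((seg_kind, region.event_time, inside[0].time))
        else:
            # multiple events, or a wrong-kind event: the segment scores FP
            counts.fp[seg_kind] += 1
    return counts, pairs


@dataclass(frozen=True)
class MetricsReport:
    """Detection metrics: per-kind TPR (fractions), pooled F1 on the 0-100
    scale, per-kind RMSD timing bias in ms (None when no TP pairs exist),
    and the raw counts."""

    onset_tpr: Optional[float]
    offset_tpr: Optional[float]
    f1: float
    onset_bias: Optional[float]
    offset_bias: Optional[float]
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "onset_tpr": self.onset_tpr,
            "offset_tpr": self.offset_tpr,
            "f1": self.f1,
            "onset_bias_ms": self.onset_bias,
            "offset_bias_ms": self.offset_bias,
            "tp": self.counts.tp_total,
            "fn": self.counts.fn_total,
            "fp": self.counts.fp_total,
            "tn": self.counts.tn,
            "n_true_onsets": self.counts.n_true[ONSET],
            "n_true_offsets": self.counts.n_true[OFFSET],
            "n_detected_onsets": self.counts.n_detected[ONSET],
            "n_detected_offsets": self.counts.n_detected[OFFSET],
        }


def _rmsd_ms(pairs, kind: str) -> Optional[float]:
    errs = [1000.0 * (det - true) for k, true, det in pairs if k == kind]
    if not errs:
        return None
    return float(np.sqrt(np.mean(np.square(errs))))


def compute_metrics(counts: ConfusionCounts, pairs) -> MetricsReport:
    """Assemble the metrics report from counts and matched TP pairs."""
    def tpr(kind: str) -> Optional[float]:
        n = counts.n_true[kind]
        return counts.tp[kind] / n if n else None

    denom = 2 * counts.tp_total + counts.fn_total + counts.fp_total
    f1 = 100.0 * 2 * counts.tp_total / denom if denom else 0.0
    return MetricsReport(
        onset_tpr=tpr(ONSET),
        offset_tpr=tpr(OFFSET),
        f1=f1,
        onset_bias=_rmsd_ms(pairs, ONSET),
        offset_bias=_rmsd_ms(pairs, OFFSET),
        counts=counts,
    )


def evaluate(
    detected: ChangePointSet,
    truth: ChangePointSet,
    duration: float,
    pre_ms: float = 300.0,
    post_ms: float = 200.0,
) -> MetricsReport:
    """End-to-end scoring: build regions, classify events, compute metrics."""
    partition = build_regions(truth, duration, pre_ms, post_ms)
    counts, pairs = classify_events(detected, partition)
    return compute_metrics(counts, pairs)
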