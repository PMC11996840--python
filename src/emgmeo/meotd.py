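"""MEOTD: the multi-resolution energy operator + double-threshold monitor.

Pipeline: multi-resolution energy operator → median conditioning → baseline
noise-statistics threshold → double-threshold scan.  The detector assumes the
first stretch of the recording is activity-free (pre-trial rest) and frames
it to estimate an amplitude threshold

    Th1 = mean(frame means) + j · mean(frame standard deviations)

where ``j`` is the threshold scaling factor trading false alarms against
detection probability.  The double-threshold scan then exploits two
physiological facts: a voluntary contraction lasts at least ~100 ms (``Ton``)
and the switch from rest to the next activation takes at least ~25-30 ms
(``Toff``).  An onset is declared at the earliest sample followed by ``Ton``
consecutive supra-threshold samples; the paired offset at the earliest later
sample followed by ``Toff`` consecutive sub-threshold samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditioning import median_filter
from .energy import EnergySeries, mteo
from .signal import OFFSET, ONSET, ChangePointSet, Signal, ms_to_samples


@dataclass(frozen=True)
class BaselineModel:
    """Noise statistics of the activity-free prefix and the derived threshold.

    ``frame_means``/``frame_stds`` are per-frame statistics (population sd)
    of the conditioned energy over the first ``baseline_len`` samples framed
    with window ``frame_len`` and hop ``step``; ``th1`` is the detection
    threshold in energy units.
    """

    baseline_len: int
    frame_len: int
    step: int
    j: float
    frame_means: np.ndarray
    frame_stds: np.ndarray
    th1: float

    @property
    def n_frames(self) -> int:
        return self.frame_means.size


@dataclass(frozen=True)
class DoubleThresholdConfig:
    """MEOTD parameters.

    Durations are stored in milliseconds and converted to samples at run
    time (round(ms·fs/1000)), so a configuration is sampling-rate agnostic.

    Attributes
    ----------
    ton_ms, toff_ms : float
        Minimum supra-threshold run to declare an onset (default 100 ms, the
        minimum voluntary contraction duration) and minimum sub-threshold run
        to declare an offset (default 30 ms, the minimum contraction
        switching time).
    j : float
        Threshold scaling factor.
    k_max, median_len : int
        Energy-operator maximum lag and median window (samples).
    baseline_ms : float
        Length of the activity-free prefix used for noise estimation.
    frame_len, step : int
        Baseline framing window and hop, in samples.
    """

    ton_ms: float = 100.0
    toff_ms: float = 30.0
    j: float = 5.0
    k_max: int = 15
    median_len: int = 15
    rectified: bool = False
    baseline_ms: float = 1000.0
    frame_len: int = 128
    step: int = 64
    scales: str = "all"
    median_mode: str = "sliding"

    def __post_init__(self) -> None:
        if not self.toff_ms > 0 or self.ton_ms < self.toff_ms:
            raise ValueError(f"need ton_ms >= toff_ms > 0, got {self.ton_ms}, {self.toff_ms}")


def estimate_baseline(
    energy: EnergySeries,
    baseline_len: int,
    frame_len: int,
    step: int,
    j: float,
) -> BaselineModel:
    """Estimate the detection threshold from the activity-free prefix.

    Frames ``energy[:baseline_len]`` with window ``frame_len`` and hop
    ``step`` (``floor((baseline_len − frame_len)/step) + 1`` frames), and sets
    ``th1 = mean(frame means) + j * mean(frame population sds)``.
    """
    if frame_len < 1 or step < 1:
        raise ValueError("frame_len and step must be >= 1")
    if baseline_len < frame_len:
        raise ValueError(
            f"baseline length {baseline_len} shorter than frame length {frame_len}"
        )
    if baseline_len > len(energy):
        raise ValueError("baseline extends beyond the energy series")
    prefix = energy.values[:baseline_len]
    n_frames = (baseline_len - frame_len) // step + 1
    starts = np.arange(n_frames) * step
    frames = np.stack([prefix[s:s + frame_len] for s in starts])
    means = frames.mean(axis=1)
    stds = frames.std(axis=1)  # population sd
    th1 = float(means.mean() + j * stds.mean())
    return BaselineModel(baseline_len, frame_len, step, float(j), means, stds, th1)


def _run_lengths(b: np.ndarray) -> np.ndarray:
    """For each index i, the length of the run of True values starting at i."""
    n = b.size
    ends = np.flatnonzero(~b)  # first False at or after i
    nxt = np.full(n, n)
    if ends.size:
        pos = np.searchsorted(ends, np.arange(n))
        valid = pos < ends.size
        nxt[valid] = ends[pos[valid]]
    out = np.where(b, nxt - np.arange(n), 0)
    return out


def double_threshold_scan(
    energy: EnergySeries,
    th1: float,
    ton_samples: int,
    toff_samples: int,
) -> ChangePointSet:
    """Left-to-right double-threshold scan over a conditioned energy series.

    An onset is the earliest index ``E_n`` whose next ``ton_samples`` values
    all strictly exceed ``th1``; the paired offset is the earliest ``E_m >
    E_n`` whose next ``toff_samples`` values are all strictly below ``th1``
    (ties at exactly ``th1`` count as below threshold for the onset test and
    as not-below for the offset test).  The scan resumes after ``E_m +
    toff_samples``.  A trailing activity with no qualifying offset is closed
    at the final sample.  Returns an empty set when nothing qualifies.
    """
    if ton_samples < 1 or toff_samples < 1:
        raise ValueError("ton_samples and toff_samples must be >= 1")
    x = energy.values
    n = x.size
    above = x > th1
    run_above = _run_lengths(above)
    run_below = _run_lengths(~above)
    onset_ok = np.flatnonzero(run_above >= ton_samples)
    offset_ok = np.flatnonzero(run_below >= toff_samples)

    kinds: list = []
    indices: list = []
    i = 0
    while True:
        p = np.searchsorted(onset_ok, i)
        if p == onset_ok.size:
            break
        en = int(onset_ok[p])
        q = np.searchsorted(offset_ok, en + 1)
        if q == offset_ok.size:
            # trailing unclosed activity: close at the final sample (a
            # degenerate onset at the very last sample is dropped)
            if en < n - 1:
                kinds.extend((ONSET, OFFSET))
                indices.extend((en, n - 1))
            break
        kinds.append(ONSET)
        indices.append(en)
        em = int(offset_ok[q])
        kinds.append(OFFSET)
        indices.append(em)
        i = em + toff_samples
    return ChangePointSet.from_samples(kinds, indices, energy.fs)


def meotd_detect(signal: Signal, config: DoubleThresholdConfig = DoubleThresholdConfig()) -> ChangePointSet:
    """Run the full MEOTD pipeline on a signal.

    Composes the multi-resolution energy operator, median conditioning,
    baseline threshold estimation and the double-threshold scan, with all
    millisecond parameters converted at the configured sampling rate.
    """
    fs = signal.fs
    energy = mteo(signal, config.k_max, rectified=config.rectified, scales=config.scales)
    energy = median_filter(energy, config.median_len, mode=config.median_mode)
    baseline_len = ms_to_samples(config.baseline_ms, fs)
    model = estimate_baseline(energy, baseline_len, config.frame_len, config.step, config.j)
    ton = max(1, ms_to_samples(config.ton_ms, fs))
    toff = max(1, ms_to_samples(config.toff_ms, fs))
    return double_threshold_scan(energy, model.th1, ton, toff)
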