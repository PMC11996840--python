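"""Labeled synthetic surface-EMG recordings and analytic test signals.

Real labeled surface-EMG corpora are scarce (and the hardware-synchronized
recordings this package targets are not public), so the generator emulates a
typical wrist-muscle acquisition: a 1,024 Hz single-channel trace consisting
of a Gaussian sensor-noise floor plus ~30 voluntary contractions per
two-minute recording.  Each contraction is modeled as band-limited Gaussian
noise (the standard amplitude-modulated surrogate for surface EMG, default
band 20-450 Hz) scaled to a target SNR and shaped by a trapezoidal envelope
whose linear ramps give an unambiguous ground-truth onset (the ramp start).

Bursts are kept >= 0.6 s apart so the region-based evaluation windows
(300 ms before / 200 ms after each true change-point) never overlap, and the
first burst starts no earlier than 2 s so threshold detectors have an
activity-free prefix to estimate their noise statistics from.

Pure sinusoids are provided as closed-form oracles for the energy operators:
on A·cos(ωn+φ) the lag-k operator returns the constant A²·sin²(kω).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal import ChangePointSet, Signal

MIN_BURST_S = 0.2      # shortest representable contraction
MIN_GAP_S = 0.6        # keeps evaluation regions disjoint
DEFAULT_BAND = (20.0, 450.0)
DEFAULT_RAMP_S = 0.05
DEFAULT_FS = 1024.0


@dataclass(frozen=True)
class SinusoidSpec:
    """A·cos(ωn + φ) over n = 0..length−1 (ω in radians/sample)."""

    amplitude: float
    angular_frequency: float
    phase: float = 0.0
    length: int = 128

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 < self.angular_frequency < np.pi:
            raise ValueError("angular frequency must lie in (0, pi) radians/sample")
        if self.length < 3:
            raise ValueError("length must be >= 3")


def generate_sinusoid(spec: SinusoidSpec, fs: float = DEFAULT_FS) -> Signal:
    """Exact cosine samples for the given spec."""
    n = np.arange(spec.length)
    return Signal(spec.amplitude * np.cos(spec.angular_frequency * n + spec.phase), fs)


@dataclass(frozen=True)
class BurstSpec:
    """One voluntary contraction.

    ``amplitude`` (the burst's target standard deviation, signal units) may
    be None, in which case it is derived from the recording-level SNR as
    σ_a = σ_b·10^(snr/20).  ``band`` is the burst's spectral support in Hz;
    ``ramp_s`` the linear rise/fall time of the trapezoidal envelope.
    """

    onset: float
    offset: float
    amplitude: Optional[float] = None
    band: tuple = DEFAULT_BAND
    ramp_s: float = DEFAULT_RAMP_S

    def __post_init__(self) -> None:
        if self.offset - self.onset < MIN_BURST_S:
            raise ValueError(
                f"burst [{self.onset}, {self.offset}] shorter than {MIN_BURST_S} s"
            )
        if self.onset < 0:
            raise ValueError("burst onset must be >= 0")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")
        if self.ramp_s < 0:
            raise ValueError("ramp must be >= 0")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated signal together with its ground truth and parameters."""

    signal: Signal
    truth: ChangePointSet
    bursts: tuple
    baseline_sigma: float
    snr_db: float
    seed: Optional[int]


def random_bursts(
    n_bursts: int,
    duration: float,
    rng: np.random.Generator,
    min_duration: float = 0.5,
    max_duration: float = 2.0,
    first_onset: float = 2.0,
    min_gap: float = MIN_GAP_S,
    band: tuple = DEFAULT_BAND,
    ramp_s: float = DEFAULT_RAMP_S,
) -> list:
    """Draw ``n_bursts`` non-overlapping bursts with random durations and
    random extra spacing, filling ``[first_onset, duration]``."""
    durs = rng.uniform(min_duration, max_duration, n_bursts)
    slack = duration - 0.5 - first_onset - durs.sum() - min_gap * (n_bursts - 1)
    if slack < 0:
        raise ValueError(
            f"{n_bursts} bursts of up to {max_duration} s do not fit in {duration} s"
        )
    extra = rng.dirichlet(np.ones(n_bursts)) * slack
    bursts = []
    t = first_onset
    for d, e in zip(durs, extra):
        bursts.append(BurstSpec(t, t + d, band=band, ramp_s=ramp_s))
        t += d + min_gap + e
    return bursts


def _validate_bursts(bursts: Sequence[BurstSpec], duration: float, fs: float) -> None:
    prev_off = None
    for b in bursts:
        if b.offset > duration:
            raise ValueError(f"burst [{b.onset}, {b.offset}] extends past {duration} s")
        if not b.band[1] < fs / 2:
            raise ValueError(f"band {b.band} not inside (0, fs/2) at fs={fs}")
        if prev_off is not None and b.onset - prev_off < MIN_GAP_S:
            raise ValueError(
                f"bursts overlap or are closer than {MIN_GAP_S} s "
                f"(gap {b.onset - prev_off:.3f} s)"
            )
        prev_off = b.offset


def generate_recording(
    fs: float = DEFAULT_FS,
    duration: float = 120.0,
    bursts: Optional[Sequence[BurstSpec]] = None,
    baseline_sigma: float = 1.0,
    snr_db: float = 20.0,
    seed: Optional[int] = None,
    n_bursts: int = 30,
) -> SyntheticRecording:
    """Generate a labeled synthetic surface-EMG recording.

    The signal is Gaussian baseline noise (sd ``baseline_sigma``) everywhere
    plus, inside each burst, zero-phase band-pass-filtered Gaussian noise
    scaled to sd σ_a = σ_b·10^(snr/20) (or the burst's explicit amplitude)
    and shaped by a trapezoidal envelope.  The same seed reproduces the
    recording bit for bit.

    When ``bursts`` is None, ``n_bursts`` bursts of 0.5-2 s are placed at
    random with >= 0.6 s separation, starting no earlier than 2 s.
    """
    if baseline_sigma < 0:
        raise ValueError("baseline_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if bursts is None:
        bursts = random_bursts(n_bursts, duration, rng)
    bursts = tuple(bursts)
    _validate_bursts(bursts, duration, fs)

    n = int(round(duration * fs))
    x = rng.normal(0.0, baseline_sigma, n) if baseline_sigma > 0 else np.zeros(n)

    pad = 128  # filter warm-up samples discarded on each side
    for b in bursts:
        sigma_a = b.amplitude
        if sigma_a is None:
            sigma_a = baseline_sigma * 10.0 ** (snr_db / 20.0)
        i0, i1 = int(round(b.onset * fs)), int(round(b.offset * fs))
        m = i1 - i0
        sos = butter(4, b.band, btype="band", fs=fs, output="sos")
        raw = rng.normal(0.0, 1.0, m + 2 * pad)
        bp = sosfiltfilt(sos, raw)[pad:pad + m]
        sd = bp.std()
        if sd > 0 and sigma_a > 0:
            bp = bp * (sigma_a / sd)
        else:
            bp = np.zeros(m)
        ramp_n = b.ramp_s * fs
        idx = np.arange(m)
        if ramp_n > 0:
            env = np.minimum(1.0, np.minimum(idx / ramp_n, (m - 1 - idx) / ramp_n))
            env = np.maximum(env, 0.0)
        else:
            env = np.ones(m)
        x[i0:i1] += bp * env

    truth = ChangePointSet.from_pairs([(b.onset, b.offset) for b in bursts], fs)
    return SyntheticRecording(
        Signal(x, fs), truth, bursts, float(baseline_sigma), float(snr_db), seed
    )


def baseline_mask(recording: SyntheticRecording) -> np.ndarray:
    """Boolean mask of samples outside every burst (baseline only)."""
    sig = recording.signal
    mask = np.ones(len(sig), dtype=bool)
    for b in recording.bursts:
        i0, i1 = int(round(b.onset * sig.fs)), int(round(b.offset * sig.fs))
        mask[i0:i1] = False
    return mask
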