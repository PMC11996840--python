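"""MEONND: the fixed-weight, network-style energy-operator monitor.

The detector recasts the multi-resolution energy operator as a small
feed-forward network with frozen weights, so no training data or baseline
prior is needed:

1. *Convolution channels with squared activation*: one channel per lag k,

       C_k(n) = W1·(w11·x_{n+k})² + W2·(w22·x_n)² + W3·(w33·x_{n−k})²
              + W4·(w14·x_{n+k} + w34·x_{n−k})²

   With the canonical weights (W1=W2=W3=1, W4=−1, w11=w14=2, w22=1,
   w33=w34=1/4) the cross terms cancel exactly and C_k ≡ Ψ_k(x_n) =
   x_n² − x_{n+k}·x_{n−k}, the lag-k energy operator.
2. *Max pooling* across channels (the multi-resolution pool).
3. *Order-statistics conditioning* (median filter), applied to the pooled
   series by default, or per channel before pooling.
4. *Sampling layer*: min-max normalization of the pooled energy into [0, 1].
5. *Sigmoid + hard limiter*: a sample is active iff sigmoid(y) >= T.
6. *Physiological post-processing*: activations shorter than the minimum
   contraction switching time (default 30 ms) are discarded.

Because every stage is homogeneous or normalized, the detector is invariant
to global amplitude scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .conditioning import median_filter
from .energy import EnergySeries, _check_scale, _psi
from .signal import OFFSET, ONSET, ChangePointSet, Signal, ms_to_samples

_CANONICAL = (1.0, 1.0, 1.0, -1.0, 2.0, 2.0, 1.0, 0.25, 0.25)


@dataclass(frozen=True)
class NetworkWeights:
    """Frozen neuron weights of the energy-operator convolution layer.

    The only admissible values are the canonical ones that make the layer
    identical to the lag-k energy operator; anything else is rejected, since
    the layer is fixed by construction rather than trained.
    """

    W1: float = 1.0
    W2: float = 1.0
    W3: float = 1.0
    W4: float = -1.0
    w11: float = 2.0
    w14: float = 2.0
    w22: float = 1.0
    w33: float = 0.25
    w34: float = 0.25

    def __post_init__(self) -> None:
        got = (self.W1, self.W2, self.W3, self.W4, self.w11, self.w14, self.w22, self.w33, self.w34)
        if got != _CANONICAL:
            raise ValueError(
                "non-canonical network weights: the convolution layer is fixed at "
                f"{_CANONICAL}, got {got}"
            )


@dataclass(frozen=True)
class MEONNDConfig:
    """MEONND parameters.

    Attributes
    ----------
    k_max : int
        Number of convolution channels (lags 1..k_max).
    median_len : int
        Order-statistics window (samples, odd).
    threshold : float
        Hard-limiter threshold T on the sigmoid output, in (0, 1).  Only
        values above 0.5 discriminate, since sigmoid maps [0, 1] into
        [0.5, 0.731].
    min_on_ms : float
        Minimum activation duration; shorter 1-runs are discarded.
    norm : {"global", "running", "trailing"}
        Sampling-layer normalization window: whole series (default), causal
        expanding window, or the trailing window of 2·k_max samples.
    median_stage : {"pooled", "per_channel"}
        Where the median filter runs: once on the pooled series (default) or
        on each channel before pooling.
    """

    k_max: int = 15
    median_len: int = 15
    threshold: float = 0.506
    min_on_ms: float = 30.0
    rectified: bool = False
    norm: str = "global"
    median_stage: str = "pooled"
    scales: str = "all"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.norm not in ("global", "running", "trailing"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.median_stage not in ("pooled", "per_channel"):
            raise ValueError(f"unknown median_stage {self.median_stage!r}")


def conv_energy_layer(
    signal: Signal, k: int, weights: NetworkWeights = NetworkWeights()
) -> EnergySeries:
    """One convolution channel with squared activation, evaluated literally.

    Computed term by term from the neuron expression (not by calling the
    energy operator), so the algebraic identity ``C_k ≡ Ψ_k`` is a real
    cross-check rather than a tautology.  Boundary samples (within ``k`` of
    either end) are 0.
    """
    x = signal.samples
    _check_scale(x.size, k)
    xp = x[2 * k:]   # x_{n+k} for interior n
    x0 = x[k:-k]     # x_n
    xm = x[: -2 * k]  # x_{n-k}
    w = weights
    interior = (
        w.W1 * (w.w11 * xp) ** 2
        + w.W2 * (w.w22 * x0) ** 2
        + w.W3 * (w.w33 * xm) ** 2
        + w.W4 * (w.w14 * xp + w.w34 * xm) ** 2
    )
    out = np.zeros_like(x)
    out[k:-k] = interior
    return EnergySeries(out, signal.fs, k, False)


def _pool_channels(signal: Signal, config: MEONNDConfig, weights: NetworkWeights) -> EnergySeries:
    """Max-pool the convolution channels, each sample over its defined lags."""
    x = signal.samples
    _check_scale(x.size, config.k_max)
    ks = range(1, config.k_max + 1) if config.scales == "all" else range(1, config.k_max + 1, 2)
    out = np.zeros_like(x)
    first = True
    for k in ks:
        ck = conv_energy_layer(signal, k, weights)
        if config.rectified:
            ck = ck.with_values(np.abs(ck.values))
        if config.median_stage == "per_channel":
            ck = median_filter(ck, config.median_len)
        vals = ck.values[k:-k]
        if first:
            out[k:-k] = vals
            first = False
        else:
            np.maximum(out[k:-k], vals, out=out[k:-k])
    return EnergySeries(out, signal.fs, config.k_max, config.rectified)


def _sampling_layer(x: np.ndarray, k_max: int, norm: str) -> np.ndarray:
    """Min-max normalize the pooled energy into [0, 1].

    Degenerate windows (max == min) map to 0.  For the trailing mode the
    window is the 2·k_max samples ending at the current one, truncated to the
    available prefix at the start of the series.
    """
    if norm == "global":
        mn, mx = x.min(), x.max()
        if mx == mn:
            return np.zeros_like(x)
        return (x - mn) / (mx - mn)
    if norm == "running":
        mn = np.minimum.accumulate(x)
        mx = np.maximum.accumulate(x)
    else:  # trailing
        w = 2 * k_max
        mn = sliding_window_view(np.concatenate([np.full(w - 1, np.inf), x]), w).min(axis=1)
        mx = sliding_window_view(np.concatenate([np.full(w - 1, -np.inf), x]), w).max(axis=1)
    rng = mx - mn
    safe = np.where(rng > 0, rng, 1.0)
    return np.where(rng > 0, (x - mn) / safe, 0.0)


def meonnd_forward(
    signal: Signal,
    config: MEONNDConfig = MEONNDConfig(),
    weights: NetworkWeights = NetworkWeights(),
) -> np.ndarray:
    """Forward pass: channels → max pool → median → sampling layer.

    Returns the normalized series y with every value in [0, 1].
    """
    if len(signal) <= 2 * config.k_max:
        raise ValueError("signal must be longer than 2*k_max samples")
    pooled = _pool_channels(signal, config, weights)
    if config.median_stage == "pooled":
        pooled = median_filter(pooled, config.median_len)
    return _sampling_layer(pooled.values, config.k_max, config.norm)


def classify(y: np.ndarray, threshold: float) -> np.ndarray:
    """Sigmoid + hard limiter: mask_i = 1 iff 1/(1+exp(−y_i)) >= T."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    sig = 1.0 / (1.0 + np.exp(-np.asarray(y, dtype=np.float64)))
    return (sig >= threshold).astype(np.int8)


def postprocess_mask(mask: np.ndarray, min_duration_ms: float, fs: float) -> np.ndarray:
    """Discard activations shorter than the minimum contraction duration.

    Every maximal run of 1s shorter than round(min_duration_ms·fs/1000)
    samples is zeroed; nothing else changes (short gaps are not merged).
    """
    mask = np.asarray(mask).astype(np.int8)
    min_len = ms_to_samples(min_duration_ms, fs)
    if min_len <= 1:
        return mask.copy()
    out = mask.copy()
    d = np.diff(np.concatenate(([0], out, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    for s, e in zip(starts, stops):
        if e - s < min_len:
            out[s:e] = 0
    return out


def mask_to_events(mask: np.ndarray, fs: float) -> ChangePointSet:
    """Extract change-points: onset at each 0→1 transition (first active
    sample), offset at each 1→0 transition (first inactive sample); a run
    still open at the end of the mask is closed at the last sample."""
    mask = np.asarray(mask).astype(np.int8)
    d = np.diff(np.concatenate(([0], mask, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    kinds: list = []
    indices: list = []
    n = mask.size
    for s, e in zip(starts, stops):
        off = int(e) if e < n else n - 1
        if off <= s:
            continue  # degenerate single-sample run at the array end
        kinds.extend((ONSET, OFFSET))
        indices.extend((int(s), off))
    return ChangePointSet.from_samples(kinds, indices, fs)


def meonnd_detect(
    signal: Signal,
    config: MEONNDConfig = MEONNDConfig(),
    weights: NetworkWeights = NetworkWeights(),
) -> ChangePointSet:
    """Run the full MEONND pipeline: forward → classify → post-process →
    change-point extraction."""
    y = meonnd_forward(signal, config, weights)
    mask = classify(y, config.threshold)
    mask = postprocess_mask(mask, config.min_on_ms, signal.fs)
    return mask_to_events(mask, signal.fs)
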