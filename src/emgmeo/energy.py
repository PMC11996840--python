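"""Teager-Kaiser energy operators: TKEO, the lag-k generalization and the
multi-resolution (max-pooled) MTEO.

The classic TKEO estimates a frequency-weighted instantaneous energy from a
three-sample window, ``Ψ(x_n) = x_n² − x_{n+1}·x_{n−1}``; on a pure sinusoid
``A·cos(ωn)`` it returns the constant ``A²·sin²(ω) ≈ A²ω²``.  The lag-k
variant widens the window, making the operator sensitive to lower
frequencies, and the multi-resolution operator pools several lags with a
pointwise maximum so a single output series responds across the EMG band.

Boundary convention: samples within ``k`` of either array end, where
``x_{n±k}`` would fall outside the signal, are set to 0 for that lag; the
multi-resolution pool at such samples uses only the lags that are defined
there.  No samples are fabricated, and the edges carry no spurious energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import Signal


@dataclass(frozen=True)
class EnergySeries:
    """Per-sample energy output, aligned index-for-index with its source.

    ``values`` has signal-units² and the same length as the source signal;
    ``scale`` records the lag (or maximum lag) used; ``rectified`` flags the
    full-wave-rectified (absolute-value) variant, which is nonnegative.
    """

    values: np.ndarray
    fs: float
    scale: int
    rectified: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("energy series must be one-dimensional")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "EnergySeries":
        return EnergySeries(values, self.fs, self.scale, self.rectified)


def _check_scale(n: int, k: int) -> None:
    if k < 1:
        raise ValueError(f"lag k must be a positive integer, got {k}")
    if k > (n - 1) // 2:
        raise ValueError(f"lag k={k} too large for signal of length {n} (max {(n - 1) // 2})")


def _psi(x: np.ndarray, k: int) -> np.ndarray:
    """Interior lag-k energy x_n² − x_{n+k}·x_{n−k} for n in [k, len−1−k]."""
    return x[k:-k] ** 2 - x[2 * k:] * x[: -2 * k]


def kteo(signal: Signal, k: int = 1, rectified: bool = False) -> EnergySeries:
    """Lag-k Teager-Kaiser energy operator.

    Parameters
    ----------
    signal : Signal
        Input trace of length ``n >= 2k+1``.
    k : int
        Lag (time distance, in samples, between the outer samples and the
        centre sample).  ``k=1`` is the classic TKEO.
    rectified : bool
        If True, return the full-wave-rectified (absolute-value) output.

    Returns
    -------
    EnergySeries
        Same length as the input; the ``k`` boundary samples at each end are 0.
    """
    x = signal.samples
    _check_scale(x.size, k)
    out = np.zeros_like(x)
    out[k:-k] = _psi(x, k)
    if rectified:
        np.abs(out, out=out)
    return EnergySeries(out, signal.fs, k, rectified)


def mteo(
    signal: Signal,
    k_max: int,
    rectified: bool = False,
    scales: str = "all",
) -> EnergySeries:
    """Multi-resolution energy operator: pointwise maximum over lag-k outputs.

    Parameters
    ----------
    signal : Signal
    k_max : int
        Largest lag pooled.
    rectified : bool
        Pool the rectified per-lag outputs instead.
    scales : {"all", "odd"}
        Which lags in 1..k_max enter the pool.  "all" is the default
        (the literal multi-resolution definition); "odd" restricts the pool
        to odd lags, matching parameter sweeps quoted in odd steps.

    Notes
    -----
    Each sample pools only the lags defined at that sample (a sample at
    distance ``d < k_max`` from an array end pools lags ``<= d``); the first
    and last samples, where no lag is defined, are 0.
    """
    x = signal.samples
    _check_scale(x.size, k_max)
    if scales not in ("all", "odd"):
        raise ValueError(f"scales must be 'all' or 'odd', got {scales!r}")
    ks = range(1, k_max + 1) if scales == "all" else range(1, k_max + 1, 2)

    out = np.zeros_like(x)
    first = True
    for k in ks:
        pk = _psi(x, k)
        if rectified:
            pk = np.abs(pk)
        if first:
            out[k:-k] = pk
            first = False
        else:
            np.maximum(out[k:-k], pk, out=out[k:-k])
    return EnergySeries(out, signal.fs, k_max, rectified)
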