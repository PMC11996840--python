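"""Order-statistics conditioning of energy series.

Energy operators amplify isolated noise samples into large spikes (the
amplitude/frequency demodulation underlying the operator degenerates when the
local energy of the derivative vanishes).  A mean filter smears such spikes
instead of removing them; a median filter annihilates any spike narrower than
half its window, which is why order statistics is used here.

Two windowing modes are provided:

* ``"sliding"`` (default): a hop-1 centred sliding median, so the output
  stays sample-aligned for per-sample change-point detection.  Near the
  edges the window shrinks symmetrically to the available samples and is
  always odd, so no padding values are invented.
* ``"frame"``: non-overlapping frames of length L, each output sample set to
  the median of its frame.  Coincides with the sliding mode at frame centres.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .energy import EnergySeries


def _check_window(L: int, n: int) -> None:
    if L < 3 or L % 2 == 0:
        raise ValueError(f"median window length must be odd and >= 3, got {L}")
    if L > n:
        raise ValueError(f"median window length {L} exceeds series length {n}")


def median_filter(energy: EnergySeries, L: int, mode: str = "sliding") -> EnergySeries:
    """Median-filter an energy series with window length ``L`` (odd).

    Returns a series of the same length.  See module docstring for the two
    windowing modes and the shrinking-window edge rule.
    """
    x = energy.values
    _check_window(L, x.size)
    if mode == "sliding":
        out = _sliding_median(x, L)
    elif mode == "frame":
        out = _frame_median(x, L)
    else:
        raise ValueError(f"mode must be 'sliding' or 'frame', got {mode!r}")
    return energy.with_values(out)


def _sliding_median(x: np.ndarray, L: int) -> np.ndarray:
    h = L // 2
    out = np.empty_like(x)
    out[h:x.size - h] = np.median(sliding_window_view(x, L), axis=1)
    # shrinking symmetric (always odd) windows at the edges
    for i in range(h):
        out[i] = np.median(x[: 2 * i + 1])
        out[x.size - 1 - i] = np.median(x[x.size - 2 * i - 1:])
    return out


def _frame_median(x: np.ndarray, L: int) -> np.ndarray:
    out = np.empty_like(x)
    for start in range(0, x.size, L):
        stop = min(start + L, x.size)
        out[start:stop] = np.median(x[start:stop])
    return out
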