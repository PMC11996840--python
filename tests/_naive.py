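"""Brute-force reference implementations used as independent oracles."""

import numpy as np


def naive_mteo(x, k_max):
    out = np.zeros(len(x))
    for n in range(len(x)):
        vals = [
            x[n] * x[n] - x[n + k] * x[n - k]
            for k in range(1, k_max + 1)
            if k <= n <= len(x) - 1 - k
        ]
        out[n] = max(vals) if vals else 0.0
    return out


def naive_sliding_median(x, L):
    h = L // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        hw = min(h, i, len(x) - 1 - i)
        out[i] = np.median(x[i - hw:i + hw + 1])
    return out


def naive_scan(x, th1, ton, toff):
    n = len(x)
    events = []
    i = 0
    while i <= n - ton:
        if all(x[i + t] > th1 for t in range(ton)):
            en = i
            em = None
            m = en + 1
            while m <= n - toff:
                if all(x[m + t] < th1 for t in range(toff)):
                    em = m
                    break
                m += 1
            if em is None:
                if en < n - 1:
                    events.append((en, n - 1))
                break
            events.append((en, em))
            i = em + toff
        else:
            i += 1
    return events
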