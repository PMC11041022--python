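"""Brute-force oracles shared across test modules."""

import numpy as np


def brute_force_prominences(x):
    """O(n^2) topographic prominence of every strict interior local maximum.

    For each peak, walk left and right to the next strictly higher sample
    (or the window edge), take the minimum of the trace on each walk; the
    prominence is peak height minus the larger of the two minima.
    """
    peaks, proms = [], []
    n = len(x)
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            left_min = x[i]
            j = i - 1
            while j >= 0 and x[j] <= x[i]:
                left_min = min(left_min, x[j])
                j -= 1
            right_min = x[i]
            j = i + 1
            while j < n and x[j] <= x[i]:
                right_min = min(right_min, x[j])
                j += 1
            peaks.append(i)
            proms.append(x[i] - max(left_min, right_min))
    return np.array(peaks), np.array(proms)


def oracle_best_peak(x, threshold):
    peaks, proms = brute_force_prominences(x)
    if len(peaks) == 0:
        return None
    best = int(np.argmax(proms))
    if proms[best] < threshold:
        return None
    return peaks[best], proms[best]
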