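"""Greedy running-mean ppm clustering core.

Shared by cross-file peakset alignment and within-file mass-trace
consolidation (there the scan index plays the role of the file id).
"""

from __future__ import annotations

import numpy as np


def ppm_diff(mz: float, reference: float) -> float:
    """Relative mass deviation of ``mz`` from ``reference`` in ppm."""
    return abs(mz - reference) / reference * 1e6


def greedy_clusters(mz_sorted: np.ndarray, ppm_tol: float) -> list[tuple[int, int]]:
    """Cluster an ascending m/z array into half-open index ranges.

    Walks left to right; a peak joins the open cluster iff it lies within
    ``ppm_tol`` of the arithmetic mean of the peaks already admitted,
    otherwise the cluster is closed and a new one opened.  The mean is
    recomputed (as a running sum / count) after every admission.
    """
    n = len(mz_sorted)
    if n == 0:
        return []
    out: list[tuple[int, int]] = []
    start = 0
    total = float(mz_sorted[0])
    count = 1
    for i in range(1, n):
        mean = total / count
        if ppm_diff(float(mz_sorted[i]), mean) <= ppm_tol:
            total += float(mz_sorted[i])
            count += 1
        else:
            out.append((start, i))
            start = i
            total = float(mz_sorted[i])
            count = 1
    out.append((start, n))
    return out
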