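"""Sliding-window order-statistic kernels.

Both kernels keep a histogram of the integer values currently inside the
window and update it with one insertion and one deletion per shift, so a
full chromosome pass costs O(n) histogram updates plus a short median
pointer walk.  Windows are truncated at the chromosome ends (the median is
taken over however many positions remain), and the median of an even-sized
window is the lower middle element, matching a naive sort-based median at
rank ``(size - 1) // 2``.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sliding_median", "masked_dilation"]


@njit(cache=True)
def _sliding_median_impl(x: np.ndarray, half: int) -> np.ndarray:
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    if n == 0:
        return out
    maxv = 0
    for i in range(n):
        if x[i] > maxv:
            maxv = x[i]
    hist = np.zeros(maxv + 2, dtype=np.int64)
    size = 0
    med = 0  # current median value
    nless = 0  # number of in-window elements strictly below med
    hi = min(half, n - 1)
    for j in range(hi + 1):
        v = x[j]
        hist[v] += 1
        size += 1
        if v < med:
            nless += 1
    for i in range(n):
        if i > 0:
            r = i + half
            if r < n:
                v = x[r]
                hist[v] += 1
                size += 1
                if v < med:
                    nless += 1
            l = i - half - 1
            if l >= 0:
                v = x[l]
                hist[v] -= 1
                size -= 1
                if v < med:
                    nless -= 1
        k = (size - 1) // 2
        while nless > k:
            med -= 1
            nless -= hist[med]
        while nless + hist[med] <= k:
            nless += hist[med]
            med += 1
        out[i] = med
    return out


@njit(cache=True)
def _masked_dilation_impl(x: np.ndarray, mask: np.ndarray, half: int) -> np.ndarray:
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    if n == 0:
        return out
    maxv = 0
    for i in range(n):
        if x[i] > maxv:
            maxv = x[i]
    hist = np.zeros(maxv + 2, dtype=np.int64)
    size = 0
    med = 0
    nless = 0
    hi = min(half, n - 1)
    for j in range(hi + 1):
        if mask[j]:
            v = x[j]
            hist[v] += 1
            size += 1
            if v < med:
                nless += 1
    for i in range(n):
        if i > 0:
            r = i + half
            if r < n and mask[r]:
                v = x[r]
                hist[v] += 1
                size += 1
                if v < med:
                    nless += 1
            l = i - half - 1
            if l >= 0 and mask[l]:
                v = x[l]
                hist[v] -= 1
                size -= 1
                if v < med:
                    nless -= 1
        if size == 0:
            out[i] = x[i]
            continue
        k = (size - 1) // 2
        while nless > k:
            med -= 1
            nless -= hist[med]
        while nless + hist[med] <= k:
            nless += hist[med]
            med += 1
        out[i] = med if med > x[i] else x[i]
    return out


def sliding_median(x: np.ndarray, half: int) -> np.ndarray:
    """Median of ``x[max(0, i-half) : min(n, i+half+1)]`` at every i."""
    x = np.ascontiguousarray(x, dtype=np.int64)
    if x.size and x.min() < 0:
        raise ValueError("sliding_median requires non-negative integer values")
    if half < 0:
        raise ValueError("half-window must be non-negative")
    return _sliding_median_impl(x, half)


def masked_dilation(x: np.ndarray, mask: np.ndarray, half: int) -> np.ndarray:
    """``max(x[i], median of masked values in the window)`` at every i.

    Positions where *mask* is False contribute nothing to the window
    median; if a window contains no masked position the input value is
    passed through unchanged.
    """
    x = np.ascontiguousarray(x, dtype=np.int64)
    mask = np.ascontiguousarray(mask, dtype=np.bool_)
    if mask.shape != x.shape:
        raise ValueError("mask must have the same shape as the signal")
    if x.size and x.min() < 0:
        raise ValueError("masked_dilation requires non-negative integer values")
    if half < 0:
        raise ValueError("half-window must be non-negative")
    return _masked_dilation_impl(x, mask, half)
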