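"""Independent brute-force oracles used to cross-check the implementation.

Written from the textbook definitions before the package wrappers; these
deliberately avoid scipy and the package's own code paths.
"""

from __future__ import annotations


def oracle_local_maxima(x) -> list[int]:
    """Interior local maxima; a flat-topped run reports its midpoint."""
    n = len(x)
    maxima = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                maxima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return maxima


def oracle_peaks(x) -> list[dict]:
    """Peaks with prominence, left/right base and FWHM width.

    Prominence: walk outward from the apex until a strictly higher sample
    (or the signal end); the lowest sample met on each side is that
    side's base, and the prominence is the apex height above the higher
    of the two bases.  Width: at apex_height - prominence/2, with linear
    interpolation between samples, bounded by the bases.
    """
    x = [float(v) for v in x]
    out = []
    for apex in oracle_local_maxima(x):
        left_min, left_base = x[apex], apex
        i = apex - 1
        while i >= 0 and x[i] <= x[apex]:
            if x[i] < left_min:
                left_min, left_base = x[i], i
            i -= 1
        right_min, right_base = x[apex], apex
        i = apex + 1
        while i < len(x) and x[i] <= x[apex]:
            if x[i] < right_min:
                right_min, right_base = x[i], i
            i += 1
        prominence = x[apex] - max(left_min, right_min)
        h_eval = x[apex] - prominence / 2.0

        i = apex
        while i > left_base and x[i] > h_eval:
            i -= 1
        left_ip = float(i)
        if x[i] < h_eval:
            left_ip += (h_eval - x[i]) / (x[i + 1] - x[i])
        i = apex
        while i < right_base and x[i] > h_eval:
            i += 1
        right_ip = float(i)
        if x[i] < h_eval:
            right_ip -= (h_eval - x[i]) / (x[i - 1] - x[i])

        out.append(
            {
                "apex": apex,
                "prominence": prominence,
                "left_base": left_base,
                "right_base": right_base,
                "width": right_ip - left_ip,
            }
        )
    return out


def oracle_dda_line(p0, p1) -> list[tuple[int, int]]:
    """Uniform-parameter line rasterization (round-to-nearest DDA)."""
    (x0, y0), (x1, y1) = p0, p1
    n = max(abs(x1 - x0), abs(y1 - y0))
    if n == 0:
        return [(x0, y0)]
    pts = []
    for i in range(n + 1):
        t = i / n
        pts.append((round(x0 + t * (x1 - x0)), round(y0 + t * (y1 - y0))))
    return pts
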