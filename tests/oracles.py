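"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (python loops, explicit normal
equations, flood fill) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def median_oracle(frames):
    """Per-pixel sort-and-pick median; even counts average the middle two."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    rows, cols = frames[0].shape
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            vals = sorted(f[r, c] for f in frames)
            m = len(vals)
            if m % 2:
                out[r, c] = vals[m // 2]
            else:
                out[r, c] = 0.5 * (vals[m // 2 - 1] + vals[m // 2])
    return out


def baseline_oracle(curve, order):
    """Polynomial residual via explicit normal equations on [-1, 1]."""
    curve = np.asarray(curve, dtype=float)
    x = np.linspace(-1.0, 1.0, curve.size)
    v = np.vander(x, order + 1, increasing=True)
    coef = np.linalg.solve(v.T @ v, v.T @ curve)
    return curve - v @ coef


def trapz_oracle(curve, element_count):
    """Explicit trapezoid sum with unit spacing, normalized."""
    curve = np.asarray(curve, dtype=float)
    total = 0.0
    for i in range(curve.size - 1):
        total += 0.5 * (curve[i] + curve[i + 1])
    return total / element_count


def peak_scan_oracle(curve):
    """Exhaustive local-maximum scan.

    Returns (positions, heights, widths): positions are the first sample of
    each strict local maximum (plateaus included), heights the curve values,
    widths the full width at half prominence obtained by walking out to the
    bases and interpolating the crossing points.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.size
    plateaus = []  # (left_edge, right_edge) inclusive
    i = 1
    while i < n - 1:
        if curve[i] > curve[i - 1]:
            j = i
            while j < n - 1 and curve[j + 1] == curve[i]:
                j += 1
            if j < n - 1 and curve[j + 1] < curve[i]:
                plateaus.append((i, j))
            i = j + 1
        else:
            i += 1

    positions, heights, widths = [], [], []
    for left_edge, right_edge in plateaus:
        mid = (left_edge + right_edge) // 2
        h = curve[mid]
        # prominence: walk out until a higher sample or the signal edge
        i = left_edge - 1
        left_min, left_base = h, left_edge
        while i >= 0 and curve[i] <= h:
            if curve[i] < left_min:
                left_min, left_base = curve[i], i
            i -= 1
        i = right_edge + 1
        right_min, right_base = h, right_edge
        while i < n and curve[i] <= h:
            if curve[i] < right_min:
                right_min, right_base = curve[i], i
            i += 1
        prominence = h - max(left_min, right_min)
        level = h - 0.5 * prominence
        # crossing points of the horizontal line at `level`, within the bases
        i = mid
        while i > left_base and curve[i] > level:
            i -= 1
        if curve[i] <= level:
            x_left = i + (level - curve[i]) / (curve[i + 1] - curve[i])
        else:
            x_left = float(i)
        i = mid
        while i < right_base and curve[i] > level:
            i += 1
        if curve[i] <= level:
            x_right = i - (level - curve[i]) / (curve[i - 1] - curve[i])
        else:
            x_right = float(i)
        positions.append(left_edge)
        heights.append(h)
        widths.append(x_right - x_left)
    return (np.array(positions, dtype=int), np.array(heights),
            np.array(widths))


def largest_component_oracle(mask):
    """Flood-fill 8-connected labeling; returns the largest component mask."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    seen = np.zeros_like(mask)
    best, best_size = None, 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    rr, cc = stack.pop()
                    comp.append((rr, cc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < rows and 0 <= c2 < cols
                                    and mask[r2, c2] and not seen[r2, c2]):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                if len(comp) > best_size:
                    best_size, best = len(comp), comp
    out = np.zeros_like(mask)
    for rr, cc in best or []:
        out[rr, cc] = True
    return out
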