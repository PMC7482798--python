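"""Independent brute-force oracles used by the test suite.

Everything here iterates voxel-by-voxel in plain Python, deliberately
sharing no code with the package implementation.
"""

from collections import deque

import numpy as np


def brute_threshold(data, box, beta=0.3, shell=2):
    """Adaptive threshold by explicit voxel loops."""
    z0, z1, y0, y1, x0, x1 = box
    sub_vals = []
    for z in range(z0, z1):
        for y in range(y0, y1):
            for x in range(x0, x1):
                sub_vals.append(data[z, y, x])
    vmax = max(sub_vals)
    hot = [v for v in sub_vals if v > 0.70 * vmax]
    i70 = sum(hot) / len(hot)

    sz, sy, sx = data.shape
    shell_vals = []
    for z in range(max(z0 - shell, 0), min(z1 + shell, sz)):
        for y in range(max(y0 - shell, 0), min(y1 + shell, sy)):
            for x in range(max(x0 - shell, 0), min(x1 + shell, sx)):
                if z0 <= z < z1 and y0 <= y < y1 and x0 <= x < x1:
                    continue
                shell_vals.append(data[z, y, x])
    if shell_vals:
        kept = [v for v in shell_vals if v <= 0.70 * vmax]
        i_bg = (sum(kept) / len(kept)) if kept else (sum(shell_vals) / len(shell_vals))
    else:
        i_bg = 0.0
    return beta * i70 + i_bg


def brute_segment(data, box, beta=0.3, shell=2):
    """Flood fill (26-neighbourhood) from the seed-box maximum at >= T."""
    threshold = brute_threshold(data, box, beta, shell)
    z0, z1, y0, y1, x0, x1 = box
    best, seed = -np.inf, None
    for z in range(z0, z1):
        for y in range(y0, y1):
            for x in range(x0, x1):
                if data[z, y, x] > best:
                    best, seed = data[z, y, x], (z, y, x)
    mask = np.zeros(data.shape, dtype=bool)
    if best < threshold:
        return mask, threshold
    inside_box = lambda z, y, x: z0 <= z < z1 and y0 <= y < y1 and x0 <= x < x1
    queue = deque([seed])
    mask[seed] = True
    while queue:
        z, y, x = queue.popleft()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if not inside_box(nz, ny, nx):
                        continue
                    if not mask[nz, ny, nx] and data[nz, ny, nx] >= threshold:
                        mask[nz, ny, nx] = True
                        queue.append((nz, ny, nx))
    return mask, threshold


def brute_features(data, mask, spacing):
    vals = [data[z, y, x]
            for z in range(data.shape[0])
            for y in range(data.shape[1])
            for x in range(data.shape[2])
            if mask[z, y, x]]
    mtv = len(vals) * spacing[0] * spacing[1] * spacing[2] / 1000.0
    return max(vals), sum(vals) / len(vals), mtv


def brute_zscore(row):
    n = len(row)
    mean = sum(row) / n
    var = sum((v - mean) ** 2 for v in row) / (n - 1)
    sd = var ** 0.5
    return [(v - mean) / sd for v in row]


def brute_auc(scores, labels):
    """All-pairs concordance with 0.5 for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
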