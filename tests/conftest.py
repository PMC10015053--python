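import math

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_msd(x, y, k):
    """Independent oracle: all-pairs lag average by an explicit double loop."""
    vals = []
    n = len(x)
    for t in range(k, n):
        dx = x[t] - x[t - k]
        dy = y[t] - y[t - k]
        # squares spelled as products: float64 ** 2 may round differently
        vals.append(dx * dx + dy * dy)
    return math.fsum(vals) / len(vals)


def flood_fill_count(bw):
    """Independent oracle: 8-connected component count by explicit flood fill."""
    bw = np.asarray(bw, dtype=bool).copy()
    count = 0
    ny, nx = bw.shape
    for r0 in range(ny):
        for c0 in range(nx):
            if not bw[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            bw[r0, c0] = False
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < ny and 0 <= cc < nx and bw[rr, cc]:
                            bw[rr, cc] = False
                            stack.append((rr, cc))
    return count


def polygon_arc_length(vertices):
    """Independent oracle: closed-polygon perimeter by explicit segment sums."""
    total = 0.0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        total += float(np.hypot(x1 - x0, y1 - y0))
    return total
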