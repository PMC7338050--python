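"""Shared fixtures: tiny calibrated stacks and seeded random volumes."""

import numpy as np
import pytest

from ciliaq import Calibration, ImageStack


@pytest.fixture
def calibration():
    return Calibration(dx=0.21, dy=0.21, dz=0.4)


@pytest.fixture
def isotropic_calibration():
    return Calibration(dx=0.2, dy=0.2, dz=0.2)


@pytest.fixture
def two_channel_stack(calibration):
    """Deterministic 2-channel 8×16×16 stack with a bright bar in channel 0."""
    rng = np.random.default_rng(42)
    voxels = rng.integers(0, 30, size=(1, 2, 8, 16, 16)).astype(np.uint16)
    voxels[0, 0, 3:5, 6:9, 2:14] = 200  # bright bar in the marker channel
    voxels[0, 1, 3:5, 6:9, 2:14] = 80
    return ImageStack(voxels, calibration, ["marker", "cargo"], marker_channel=0)


def bfs_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Breadth-first-search connected-component oracle (independent of scipy)."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                manhattan = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            z, y, x = queue.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = current
                    queue.append((nz, ny, nx))
    return labels


def renyi_oracle(counts) -> int:
    """Exhaustive plain-loop scan of all candidate levels for each Renyi order,
    combined with the published weighting rule.  Written independently of the
    vectorized implementation (per-candidate loops, direct sums)."""
    import math

    counts = [float(c) for c in counts]
    total = sum(counts)
    p = [c / total for c in counts]
    n = len(p)
    P1 = []
    acc = 0.0
    for v in p:
        acc += v
        P1.append(acc)
    P2 = [1.0 - v for v in P1]
    eps = 2.220446049250313e-16
    first_bin = 0
    for i in range(n):
        if abs(P1[i]) >= eps:
            first_bin = i
            break
    last_bin = n - 1
    for i in range(n - 1, -1, -1):
        if abs(P2[i]) >= eps:
            last_bin = i
            break

    def scan(order):
        best, best_t = 0.0, 0
        for t in range(first_bin, last_bin + 1):
            if order == 1:
                eb = 0.0
                for i in range(0, t + 1):
                    if counts[i] != 0:
                        eb -= (p[i] / P1[t]) * math.log(p[i] / P1[t])
                eo = 0.0
                for i in range(t + 1, n):
                    if counts[i] != 0:
                        eo -= (p[i] / P2[t]) * math.log(p[i] / P2[t])
                tot = eb + eo
            else:
                if order == 0.5:
                    eb = sum(math.sqrt(p[i] / P1[t]) for i in range(0, t + 1))
                    eo = sum(math.sqrt(p[i] / P2[t]) for i in range(t + 1, n))
                else:  # order 2
                    eb = sum((p[i] * p[i]) / (P1[t] * P1[t]) for i in range(0, t + 1))
                    eo = sum((p[i] * p[i]) / (P2[t] * P2[t]) for i in range(t + 1, n))
                prod = eb * eo
                tot = (math.log(prod) if prod > 0 else 0.0) / (1.0 - order)
            if tot > best:
                best, best_t = tot, t
        return best_t

    t1, t2, t3 = sorted((scan(0.5), scan(1), scan(2)))
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    omega = P1[t3] - P1[t1]
    return int(
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * (P2[t3] + 0.25 * omega * beta[2])
    )
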