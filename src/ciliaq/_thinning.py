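"""Topology-preserving 3D binary thinning to a curve skeleton.

Sequential thinning in six directional subiterations: in each pass,
border voxels of one face direction are deleted one at a time if they
are (26, 6) simple points — foreground 26-connectivity and background
6-connectivity of the 3×3×3 neighborhood are both preserved by the
deletion (Bertrand–Malandain characterization) — and are not curve
endpoints (voxels with at most one foreground neighbor are kept, so
tube ends survive).  Deleting strictly one voxel at a time makes
topology preservation exact, and the fixed raster order within each
directional pass makes the result deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _neighbor_count(img, z, y, x):
    count = 0
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                if dz == 0 and dy == 0 and dx == 0:
                    continue
                if img[z + dz, y + dy, x + dx] == 1:
                    count += 1
    return count


@njit(cache=True)
def _foreground_components_26(nb):
    """Number of 26-connected foreground components among the 26 neighbors."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    comps = 0
    for i in range(27):
        if i == 13:
            continue
        if nb[i // 9, (i // 3) % 3, i % 3] == 0 or visited[i] == 1:
            continue
        comps += 1
        sp = 0
        stack[sp] = i
        sp += 1
        visited[i] = 1
        while sp > 0:
            sp -= 1
            j = stack[sp]
            zj, yj, xj = j // 9, (j // 3) % 3, j % 3
            for dz in range(-1, 2):
                for dy in range(-1, 2):
                    for dx in range(-1, 2):
                        z2, y2, x2 = zj + dz, yj + dy, xj + dx
                        if 0 <= z2 < 3 and 0 <= y2 < 3 and 0 <= x2 < 3:
                            k = z2 * 9 + y2 * 3 + x2
                            if k != 13 and visited[k] == 0 and nb[z2, y2, x2] == 1:
                                visited[k] = 1
                                stack[sp] = k
                                sp += 1
    return comps


@njit(cache=True)
def _background_components_6(nb):
    """6-connected background components of the 18-neighborhood that touch
    a face neighbor (6-adjacency walked within the 18-neighborhood only)."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    comps = 0
    for i in range(27):
        if i == 13:
            continue
        z, y, x = i // 9, (i // 3) % 3, i % 3
        manhattan = abs(z - 1) + abs(y - 1) + abs(x - 1)
        if manhattan != 1:  # seed only from the six face neighbors
            continue
        if nb[z, y, x] == 1 or visited[i] == 1:
            continue
        comps += 1
        sp = 0
        stack[sp] = i
        sp += 1
        visited[i] = 1
        while sp > 0:
            sp -= 1
            j = stack[sp]
            zj, yj, xj = j // 9, (j // 3) % 3, j % 3
            for step in range(6):
                dz = (step == 0) - (step == 1)
                dy = (step == 2) - (step == 3)
                dx = (step == 4) - (step == 5)
                z2, y2, x2 = zj + dz, yj + dy, xj + dx
                if 0 <= z2 < 3 and 0 <= y2 < 3 and 0 <= x2 < 3:
                    man2 = abs(z2 - 1) + abs(y2 - 1) + abs(x2 - 1)
                    if man2 == 0 or man2 > 2:  # stay inside the 18-neighborhood
                        continue
                    k = z2 * 9 + y2 * 3 + x2
                    if visited[k] == 0 and nb[z2, y2, x2] == 0:
                        visited[k] = 1
                        stack[sp] = k
                        sp += 1
    return comps


@njit(cache=True)
def _is_simple(img, z, y, x):
    nb = np.zeros((3, 3, 3), np.uint8)
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                nb[dz + 1, dy + 1, dx + 1] = img[z + dz, y + dy, x + dx]
    nb[1, 1, 1] = 0
    if _foreground_components_26(nb) != 1:
        return False
    if _background_components_6(nb) != 1:
        return False
    return True


@njit(cache=True)
def _thin_padded(img):
    """In-place thinning of a zero-padded uint8 volume.

    Each directional subiteration is two-phase: candidates are the
    simple, non-endpoint border voxels of that direction at the *start*
    of the pass, and each is deleted only after re-checking simplicity
    and the endpoint condition against the partially thinned image.
    Restricting deletions to the initial border layer peels the object
    one layer per pass from alternating sides, keeping the skeleton
    centered; the re-check keeps topology preservation exact under
    sequential deletion.
    """
    nz, ny, nx = img.shape
    dirs = np.array(
        [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
        np.int64,
    )
    cand = np.empty((nz * ny * nx, 3), np.int64)
    changed = True
    while changed:
        changed = False
        for d in range(6):
            dz, dy, dx = dirs[d, 0], dirs[d, 1], dirs[d, 2]
            n_cand = 0
            for z in range(1, nz - 1):
                for y in range(1, ny - 1):
                    for x in range(1, nx - 1):
                        if img[z, y, x] != 1:
                            continue
                        if img[z + dz, y + dy, x + dx] != 0:
                            continue  # not a border voxel in this direction
                        if _neighbor_count(img, z, y, x) <= 1:
                            continue  # curve endpoint or isolated voxel
                        if _is_simple(img, z, y, x):
                            cand[n_cand, 0] = z
                            cand[n_cand, 1] = y
                            cand[n_cand, 2] = x
                            n_cand += 1
            for k in range(n_cand):
                z, y, x = cand[k, 0], cand[k, 1], cand[k, 2]
                if _neighbor_count(img, z, y, x) <= 1:
                    continue
                if _is_simple(img, z, y, x):
                    img[z, y, x] = 0
                    changed = True
    return img


def thin3d(mask: np.ndarray) -> np.ndarray:
    """Curve skeleton of a 3D boolean volume; same shape, dtype bool."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("thin3d expects a 3D volume")
    padded = np.pad(mask, 1).astype(np.uint8)
    _thin_padded(padded)
    return padded[1:-1, 1:-1, 1:-1].astype(bool)
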