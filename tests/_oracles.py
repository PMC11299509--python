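"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's morphology route: the pore oracle
is a hand-written breadth-first flood fill, the t oracle a textbook
closed form.
"""

from __future__ import annotations

import math
from collections import deque


def flood_fill_pores(mask, cap_faces: bool = True):
    """Enclosed-pore components of a boolean 3D mask by exterior flood fill.

    The exterior is grown with 6-connectivity from every background voxel
    on the array border (side faces only when ``cap_faces``); remaining
    background voxels are pores, grouped into 26-connected components.
    Returns a list of ``set`` of ``(z, y, x)`` tuples, sorted by smallest
    voxel for reproducibility.
    """
    nz, ny, nx = mask.shape
    exterior = set()
    queue = deque()

    def seed(z, y, x):
        if not mask[z, y, x] and (z, y, x) not in exterior:
            exterior.add((z, y, x))
            queue.append((z, y, x))

    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                on_side = y in (0, ny - 1) or x in (0, nx - 1)
                on_cut = z in (0, nz - 1)
                if on_side or (on_cut and not cap_faces):
                    seed(z, y, x)
    steps6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in steps6:
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                if not mask[z2, y2, x2] and (z2, y2, x2) not in exterior:
                    exterior.add((z2, y2, x2))
                    queue.append((z2, y2, x2))

    pores = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] and (z, y, x) not in exterior:
                    pores.add((z, y, x))

    components = []
    remaining = set(pores)
    while remaining:
        start = remaining.pop()
        comp = {start}
        queue = deque([start])
        while queue:
            z, y, x = queue.popleft()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dz == dy == dx == 0:
                            continue
                        v = (z + dz, y + dy, x + dx)
                        if v in remaining:
                            remaining.remove(v)
                            comp.add(v)
                            queue.append(v)
        components.append(comp)
    components.sort(key=lambda c: min(c))
    return components


def student_t_pooled(a, b):
    """Classic pooled-variance two-sample t statistic (b minus a) and df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (mb - ma) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, df


def spheroid_surface_area(a: float, b: float) -> float:
    """Closed-form surface area of a prolate spheroid with semi-axes
    (a, b, b), a > b."""
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b**2 * (1.0 + (a / (b * e)) * math.asin(e))
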