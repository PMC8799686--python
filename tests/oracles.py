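"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: connected components
via hand-rolled union-find, the Euler characteristic via scikit-image's
configuration counting, cavities via breadth-first flood fill, and the
simple-point test via global Betti comparison before/after a deletion.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from skimage.measure import euler_number


def union_find_components(cells, code=26):
    """Partition of a cell set into code-connected groups (union-find)."""
    cells = list(map(tuple, cells))
    parent = {c: c for c in cells}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    cellset = set(cells)
    for c in cells:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    s = abs(dx) + abs(dy) + abs(dz)
                    if code == 6 and s > 1:
                        continue
                    if code == 18 and s > 2:
                        continue
                    n = (c[0] + dx, c[1] + dy, c[2] + dz)
                    if n in cellset:
                        union(c, n)
    groups = {}
    for c in cells:
        groups.setdefault(find(c), set()).add(c)
    return sorted(groups.values(), key=lambda g: (-len(g), min(g)))


def bfs_cavities(data: np.ndarray) -> int:
    """Number of 6-connected void components not reaching the array border."""
    visited = np.zeros_like(data, dtype=bool)
    shape = data.shape
    n_cav = 0
    for start in map(tuple, np.argwhere(~data)):
        if visited[start]:
            continue
        q = deque([start])
        visited[start] = True
        touches_border = False
        while q:
            c = q.popleft()
            if any(c[a] in (0, shape[a] - 1) for a in range(3)):
                touches_border = True
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                n = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
                if all(0 <= n[a] < shape[a] for a in range(3)) and not data[n] and not visited[n]:
                    visited[n] = True
                    q.append(n)
        if not touches_border:
            n_cav += 1
    return n_cav


def betti_oracle(data: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2) from union-find components, skimage Euler number and BFS cavities."""
    occ = np.argwhere(data)
    b0 = len(union_find_components(occ, code=26)) if len(occ) else 0
    b2 = bfs_cavities(data)
    chi = int(euler_number(data, connectivity=3)) if len(occ) else 0
    return (b0, b0 + b2 - chi, b2)


def deletion_is_simple(data: np.ndarray, x) -> bool:
    """Brute force: deleting x leaves the Betti triple unchanged."""
    before = betti_oracle(data)
    after_data = data.copy()
    after_data[tuple(x)] = False
    after = betti_oracle(after_data)
    return before == after
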