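"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def chebyshev_offsets(connectivity: int):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def bfs_component(values, seed, threshold, connectivity):
    """Seed's supra-threshold component by plain BFS (NaN excluded)."""
    shape = values.shape
    offs = chebyshev_offsets(connectivity)

    def supra(v):
        val = values[v]
        return not np.isnan(val) and val >= threshold

    if not supra(seed):
        return set()
    comp = {seed}
    queue = [seed]
    while queue:
        cur = queue.pop()
        for d in offs:
            nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            if all(0 <= c < s for c, s in zip(nxt, shape)) and nxt not in comp \
                    and supra(nxt):
                comp.add(nxt)
                queue.append(nxt)
    return comp


def _articulation_points(members, adj):
    """Cut vertices of the (connected) member graph; iterative Tarjan."""
    disc, low, parent = {}, {}, {}
    children = {}
    ap = set()
    timer = 0
    for start in members:
        if start in disc:
            continue
        disc[start] = low[start] = timer
        timer += 1
        children[start] = 0
        stack = [(start, iter(adj[start]))]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in disc:
                    parent[nxt] = node
                    children[node] = children.get(node, 0) + 1
                    children[nxt] = 0
                    disc[nxt] = low[nxt] = timer
                    timer += 1
                    stack.append((nxt, iter(adj[nxt])))
                    advanced = True
                    break
                if nxt != parent.get(node):
                    low[node] = min(low[node], disc[nxt])
            if not advanced:
                stack.pop()
                p = parent.get(node)
                if p is not None:
                    low[p] = min(low[p], low[node])
                    if p != start and low[node] >= disc[p]:
                        ap.add(p)
        if children[start] >= 2:
            ap.add(start)
    return ap


class _DisjointSet:
    def __init__(self):
        self.parent = {}
        self.size = {}

    def add(self, x):
        self.parent[x] = x
        self.size[x] = 1

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def brute_force_volume_roi(values, seed, target, connectivity):
    """Reference flood-fill: sweep EVERY distinct map value as a threshold
    (descending), maintaining components incrementally with union-find; the
    first (i.e. largest) threshold whose seed component reaches the target
    wins.  The component is then trimmed exactly as specified: remove the
    lowest-valued boundary voxel (lexicographic ties) whose removal keeps
    the seed connected.  Returns (members, threshold) or raises ValueError.
    """
    shape = values.shape
    offs = chebyshev_offsets(connectivity)
    cells = [tuple(map(int, c)) for c in np.argwhere(~np.isnan(values))]
    cells.sort(key=lambda c: -values[c])
    dsu = _DisjointSet()
    active = set()
    threshold = None
    i = 0
    while i < len(cells):
        # activate the whole tie group at this distinct value
        level = values[cells[i]]
        while i < len(cells) and values[cells[i]] == level:
            cell = cells[i]
            dsu.add(cell)
            active.add(cell)
            for d in offs:
                nxt = (cell[0] + d[0], cell[1] + d[1], cell[2] + d[2])
                if nxt in active:
                    dsu.union(cell, nxt)
            i += 1
        if seed in active and dsu.size[dsu.find(seed)] >= target:
            threshold = float(level)
            break
    if threshold is None:
        raise ValueError("unreachable target size")
    root = dsu.find(seed)
    members = {c for c in active if dsu.find(c) == root}
    assert members == bfs_component(values, seed, threshold, connectivity)
    members = set(members)
    while len(members) > target:
        adj = {
            v: [
                (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                for d in offs
                if (v[0] + d[0], v[1] + d[1], v[2] + d[2]) in members
            ]
            for v in members
        }
        boundary = [v for v in members
                    if v != seed and len(adj[v]) < len(offs)]
        cut = _articulation_points(members, adj)
        removed = False
        for vox in sorted(boundary, key=lambda v: (values[v], v)):
            if vox not in cut:  # removal keeps the component connected
                members.remove(vox)
                removed = True
                break
        if not removed:
            for vox in sorted(members - {seed}, key=lambda v: (values[v], v)):
                if vox not in cut:
                    members.remove(vox)
                    removed = True
                    break
        if not removed:
            raise RuntimeError("trim failed")
    return members, threshold


def loop_pearson(x, y):
    """Pearson correlation by explicit summation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def loop_within_rows(dataset_array, regions, hemis=("L", "R")):
    """Within-subject correlations for every node pair, by explicit loops.

    Returns {(subject, label_a, label_b): r} with labels 'region_hemi' and
    pairs in region-major node order.
    """
    S, R, H, T = dataset_array.shape
    nodes = [(r, h) for r in range(R) for h in range(H)]
    out = {}
    for s in range(S):
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                (ra, ha), (rb, hb) = nodes[i], nodes[j]
                la = f"{regions[ra]}_{hemis[ha]}"
                lb = f"{regions[rb]}_{hemis[hb]}"
                out[(s, la, lb)] = loop_pearson(dataset_array[s, ra, ha],
                                                dataset_array[s, rb, hb])
    return out


def loop_between_zr(dataset_array, regions, hemis=("L", "R")):
    """Between-subject averaged Fisher-z per (subject, pair), by loops."""
    import math

    S, R, H, T = dataset_array.shape
    nodes = [(r, h) for r in range(R) for h in range(H)]
    out = {}
    for s in range(S):
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                (ra, ha), (rb, hb) = nodes[i], nodes[j]
                la = f"{regions[ra]}_{hemis[ha]}"
                lb = f"{regions[rb]}_{hemis[hb]}"
                zs = []
                for other in range(S):
                    if other == s:
                        continue
                    zs.append(math.atanh(loop_pearson(
                        dataset_array[s, ra, ha], dataset_array[other, rb, hb])))
                    zs.append(math.atanh(loop_pearson(
                        dataset_array[s, rb, hb], dataset_array[other, ra, ha])))
                out[(s, la, lb)] = sum(zs) / len(zs)
    return out


def manual_holm(pvals, family_size):
    """Step-down Holm by explicit enumeration."""
    indexed = sorted(enumerate(pvals), key=lambda kv: kv[1])
    adjusted = [0.0] * len(pvals)
    prev = 0.0
    for rank, (idx, p) in enumerate(indexed):
        val = min(1.0, p * (family_size - rank))
        prev = max(prev, val)
        adjusted[idx] = prev
    return adjusted
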