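"""Independent brute-force oracles used to cross-check the implementation."""

from collections import deque

import numpy as np

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def flood_fill_grow(data, seeds, lo, hi, barrier=None, connectivity=6):
    """BFS flood fill through in-window, non-barrier voxels (reference)."""
    data = np.asarray(data)
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    out = np.zeros(data.shape, dtype=bool)
    queue = deque()
    for s in seeds:
        s = tuple(int(v) for v in s)
        out[s] = True
        queue.append(s)
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            q = (z + dz, y + dy, x + dx)
            if any(c < 0 or c >= e for c, e in zip(q, data.shape)):
                continue
            if out[q]:
                continue
            if barrier is not None and barrier[q]:
                continue
            if lo <= data[q] <= hi:
                out[q] = True
                queue.append(q)
    return out


def flood_fill_components(mask, connectivity=6):
    """Exhaustive component enumeration; returns a list of frozensets."""
    mask = np.asarray(mask, bool)
    if mask.ndim == 2:
        mask = mask[None]
        squeeze = True
    else:
        squeeze = False
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            comp.append(p)
            for off in offsets:
                q = tuple(c + d for c, d in zip(p, off))
                if any(c < 0 or c >= e for c, e in zip(q, mask.shape)):
                    continue
                if mask[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
        if squeeze:
            comp = [(y, x) for _, y, x in comp]
        comps.append(frozenset(comp))
    return comps
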