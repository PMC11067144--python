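"""Independent re-implementation of the brightest-connected-voxel rule.

Written directly from the rule's prose description, deliberately using a
different algorithmic structure from the library (no heap: the candidate
frontier is recomputed from scratch at every step), so that agreement with
the package implementation is a meaningful cross-check.
"""

import numpy as np


def _neighbors(v, connectivity):
    x, y, z = v
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                n_nonzero = (dx != 0) + (dy != 0) + (dz != 0)
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                out.append((x + dx, y + dy, z + dz))
    return out


def greedy_brightest_connected(data, box_mask, k, connectivity=26):
    """Seed at the box maximum (ties: smallest linear index, x fastest),
    then repeatedly append the brightest box voxel adjacent to the current
    set, recomputing the frontier each iteration."""
    data = np.asarray(data, dtype=float)
    nx, ny, nz = data.shape

    def lin(v):
        return v[0] + nx * (v[1] + ny * v[2])

    box = {tuple(v) for v in np.argwhere(np.asarray(box_mask, dtype=bool))}
    seed = min(box, key=lambda v: (-data[v], lin(v)))
    chosen = [seed]
    while len(chosen) < k:
        frontier = set()
        for v in chosen:
            for nb in _neighbors(v, connectivity):
                if nb in box and nb not in chosen:
                    frontier.add(nb)
        if not frontier:
            break
        chosen.append(min(frontier, key=lambda v: (-data[v], lin(v))))
    return sorted(map(tuple, chosen), key=lin)
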