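"""Independent brute-force oracles used only to validate implementations."""

from collections import deque

import numpy as np

NEIGHBOURS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBOURS_8 = NEIGHBOURS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def flood_fill_components(mask, connectivity):
    """All connected components of a boolean mask via explicit BFS."""
    offsets = NEIGHBOURS_4 if connectivity == 4 else NEIGHBOURS_8
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            comp = []
            while queue:
                y, x = queue.popleft()
                comp.append((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(comp)
    return components


def filter_particles_bruteforce(mask, min_particle_px, connectivity):
    """Size-filtered mask plus retained component count, by flood fill."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    count = 0
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_particle_px:
            count += 1
            for y, x in comp:
                out[y, x] = True
    return out, count
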