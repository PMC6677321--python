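"""Independent brute-force oracles used to cross-check fast implementations."""

from __future__ import annotations

from collections import deque

import numpy as np

_NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(mask: np.ndarray) -> list[dict]:
    """Exhaustive BFS labelling of 8-connected components.

    Returns one dict per component with keys ``pixels`` (set of (r, c)),
    ``area``, ``bbox`` (row0, col0, row1, col1 half-open) and ``centroid``,
    in order of first pixel encountered row-major.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    rows_n, cols_n = mask.shape
    for r0 in range(rows_n):
        for c0 in range(cols_n):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            pixels = set()
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                pixels.add((r, c))
                for dr, dc in _NEIGHBOURS_8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows_n and 0 <= cc < cols_n and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        q.append((rr, cc))
            rs = [p[0] for p in pixels]
            cs = [p[1] for p in pixels]
            comps.append(
                {
                    "pixels": pixels,
                    "area": len(pixels),
                    "bbox": (min(rs), min(cs), max(rs) + 1, max(cs) + 1),
                    "centroid": (float(np.mean(rs)), float(np.mean(cs))),
                }
            )
    return comps


def largest_component_centroid_oracle(mask: np.ndarray):
    """Max-area component centroid with first-pixel-row-major tie-break."""
    comps = flood_fill_components(mask)
    if not comps:
        return None
    best_area = max(c["area"] for c in comps)
    for c in comps:  # components already in first-pixel row-major order
        if c["area"] == best_area:
            return c["centroid"]
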