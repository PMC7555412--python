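"""Brute-force reference implementations used only to check the package.

Each oracle is deliberately written in the most literal way possible —
explicit queues, per-pixel loops, from-scratch distance recomputation — so it
shares no code path with the implementation it validates.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by BFS flood fill, raster-scan seed order."""
    h, w = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = np.zeros((h, w), dtype=np.int64)
    label = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and out[r, c] == 0:
                label += 1
                queue = deque([(r, c)])
                out[r, c] = label
                while queue:
                    cr, cc = queue.popleft()
                    for dr, dc in neigh:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and out[nr, nc] == 0:
                            out[nr, nc] = label
                            queue.append((nr, nc))
    return out


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Fill holes by flood-filling the background from the border (4-conn);
    unreached background pixels are holes and become foreground."""
    h, w = mask.shape
    reached = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not reached[r, c]:
                reached[r, c] = True
                queue.append((r, c))
    while queue:
        cr, cc = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = cr + dr, cc + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] and not reached[nr, nc]:
                reached[nr, nc] = True
                queue.append((nr, nc))
    return mask | ~reached


def complete_linkage_oracle(X: np.ndarray, k: int) -> np.ndarray:
    """O(N^3) agglomeration: every step recomputes each cluster pair's maximum
    member distance from the raw coordinates; ties break toward the smallest
    (i, j) pair; the merged cluster keeps position i.  Labels 1..k are
    numbered by each final cluster's smallest member row."""
    n = X.shape[0]
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        best_d = np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d:  # strict: first (smallest i, j) wins ties
                    best_d = d
                    best = (i, j)
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=np.int64)
    for new_id, cl in enumerate(sorted(clusters, key=min), start=1):
        labels[cl] = new_id
    return labels
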