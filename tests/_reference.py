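"""Independent brute-force reference implementations used as test oracles.

These deliberately use explicit Python loops and BFS flood fill — no scipy
labeling, no vectorization — so they share no code path with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


def bfs_components(frame: np.ndarray) -> list[set]:
    """Connected components (8-connectivity) of a binary frame via BFS."""
    H, W = frame.shape
    seen = set()
    components = []
    for r in range(H):
        for c in range(W):
            if frame[r, c] and (r, c) not in seen:
                comp = set()
                queue = deque([(r, c)])
                seen.add((r, c))
                while queue:
                    rr, cc = queue.popleft()
                    comp.add((rr, cc))
                    for dr, dc in NEIGHBORS_8:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < H and 0 <= nc < W and frame[nr, nc] \
                                and (nr, nc) not in seen:
                            seen.add((nr, nc))
                            queue.append((nr, nc))
                components.append(comp)
    return components


def brute_force_labels(flags: np.ndarray, min_cluster_px: int = 10,
                       context: int = 2):
    """Reference frame labeling: (qualifying list, label list).

    Labels: 1 avalanche, 0 quiescence, -1 excluded.
    """
    T = flags.shape[0]
    qualifying = []
    for t in range(T):
        comps = bfs_components(flags[t])
        qualifying.append(any(len(c) >= min_cluster_px for c in comps))
    labels = [-1] * T
    for t in range(context, T - context):
        window = qualifying[t - context:t + context + 1]
        if all(window):
            labels[t] = 1
        elif not any(window):
            labels[t] = 0
    return qualifying, labels


def brute_force_events(flags: np.ndarray, min_cluster_px: int = 10,
                       context: int = 2):
    """Reference event extraction: list of (start, end, size) tuples."""
    qualifying, labels = brute_force_labels(flags, min_cluster_px, context)
    T = flags.shape[0]
    events = []
    t = 0
    while t < T:
        if not qualifying[t]:
            t += 1
            continue
        start = t
        while t < T and qualifying[t]:
            t += 1
        end = t
        if any(labels[f] == 1 for f in range(start, end)):
            size = 0
            for f in range(start, end):
                for comp in bfs_components(flags[f]):
                    if len(comp) >= min_cluster_px:
                        size += len(comp)
            events.append((start, end, size))
    return events


def brute_force_binarize(series, threshold: float = 3.0) -> list[int]:
    """Reference point-process scan of one pixel time series."""
    out = [0]
    for t in range(1, len(series)):
        out.append(int(series[t] >= threshold and series[t - 1] < threshold))
    return out
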