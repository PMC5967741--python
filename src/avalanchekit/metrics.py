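"""Spatial entropy of intensity maps and avalanche trajectory statistics.

Spatial entropy quantifies the randomness of a cortical intensity map: for
every overlapping 10x10 pixel neighborhood fully inside the map, the
Shannon entropy −∑ p log2 p of the window's intensity histogram (equal-width
bins over [0, 1]) is computed, and the window entropies form the sample for
two-sample t-tests between conditions (e.g. awake vs anesthetized maps).

Trajectories summarize where avalanches start and end: the origin
(destination) is the cortical region containing the centroid of the largest
qualifying cluster in the event's first (last) frame; an avalanche whose
origin and destination coincide is a loop.  Counts aggregate into
occurrence rates per region pair within each group (cluster type, state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats

from .detection import AvalancheEvent
from .synthetic import REGION_LABELS, RegionMask

__all__ = [
    "EntropySample",
    "TrajectoryRecord",
    "TrajectorySummary",
    "spatial_entropy_map",
    "compare_entropy",
    "compute_trajectories",
]


@dataclass
class EntropySample:
    """Window entropies (bits) of one intensity map."""

    values: np.ndarray                       # one entropy per interior window
    positions: np.ndarray                    # (n, 2) top-left window corners
    neighborhood: int = 10
    bins: int = 10
    source: str = ""

    @property
    def max_entropy(self) -> float:
        return float(np.log2(self.bins))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"row": self.positions[:, 0],
                             "col": self.positions[:, 1],
                             "entropy_bits": self.values})


def spatial_entropy_map(values: np.ndarray, neighborhood: int = 10,
                        bins: int = 10,
                        valid_mask: np.ndarray | None = None,
                        source: str = "") -> EntropySample:
    """Shannon entropy of intensity histograms over sliding windows.

    ``values`` must lie in [0, 1].  Windows are anchored at every pixel but
    only windows fully inside the map (and, if given, fully inside
    ``valid_mask``) are scored — edge windows would otherwise need padding
    that distorts the histogram.  Entropies are in bits, bounded by
    log2(bins); a window occupying a single bin has entropy 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("map must be 2-D")
    H, W = values.shape
    if H < neighborhood or W < neighborhood:
        raise ValueError(
            f"map {H}x{W} smaller than the {neighborhood}x{neighborhood} window")
    if values.min() < -1e-9 or values.max() > 1 + 1e-9:
        raise ValueError("map must be normalized to [0, 1]")
    digit = np.minimum((np.clip(values, 0, 1) * bins).astype(int), bins - 1)
    wins = sliding_window_view(digit, (neighborhood, neighborhood))
    nr, nc = wins.shape[:2]
    flat = wins.reshape(nr * nc, neighborhood * neighborhood)
    keep = np.ones(nr * nc, dtype=bool)
    if valid_mask is not None:
        vw = sliding_window_view(np.asarray(valid_mask, bool),
                                 (neighborhood, neighborhood))
        keep = vw.reshape(nr * nc, -1).all(axis=1)
    flat = flat[keep]
    counts = np.zeros((flat.shape[0], bins), dtype=float)
    rows = np.repeat(np.arange(flat.shape[0]), flat.shape[1])
    np.add.at(counts, (rows, flat.ravel()), 1.0)
    p = counts / flat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    entropies = -terms.sum(axis=1)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    positions = np.stack([rr.ravel()[keep], cc.ravel()[keep]], axis=1)
    return EntropySample(values=entropies, positions=positions,
                         neighborhood=neighborhood, bins=bins, source=source)


def compare_entropy(sample_a, sample_b) -> tuple[float, float, int]:
    """Pooled-variance two-sample t-test on window entropies.

    Accepts :class:`EntropySample` objects or plain arrays; returns
    ``(t, p, df)`` with ``df = n_a + n_b - 2``.  Raises if either sample has
    fewer than two values or the pooled variance is zero.
    """
    a = np.asarray(getattr(sample_a, "values", sample_a), dtype=float)
    b = np.asarray(getattr(sample_b, "values", sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() != b.mean():
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return float(t), float(p), int(a.size + b.size - 2)


@dataclass
class TrajectoryRecord:
    """Origin/destination of one avalanche."""

    event_start: int
    origin: int                              # region label
    destination: int
    displacement: tuple                      # (drow, dcol), first -> last centroid
    loop: bool = False
    group: str = "all"


@dataclass
class TrajectorySummary:
    """Per-event records plus per-group (origin, destination) rates."""

    records: list
    table: pd.DataFrame                      # group, origin, destination, count, rate

    def rates(self, group: str = "all") -> pd.DataFrame:
        return self.table[self.table["group"] == group]


def _nearest_region_lookup(mask: RegionMask) -> np.ndarray:
    """Label map where background pixels carry the nearest region's label."""
    background = mask.labels == 0
    if not background.any():
        return mask.labels
    _, (ir, ic) = ndimage.distance_transform_edt(background, return_indices=True)
    return mask.labels[ir, ic]


def compute_trajectories(events: list[AvalancheEvent], mask: RegionMask,
                         group_labels=None) -> TrajectorySummary:
    """Extract origin/destination trajectories from detected avalanches.

    The origin (destination) region is the one containing the centroid of
    the largest qualifying cluster in the first (last) frame of the event,
    taken directly from the point-process clusters.  A centroid landing on
    background is assigned the nearest region with a warning.  Rates are
    normalized within each group and sum to 1 there.
    """
    if group_labels is None:
        group_labels = ["all"] * len(events)
    if len(group_labels) != len(events):
        raise ValueError("one group label per event required")
    lookup = _nearest_region_lookup(mask)
    records: list[TrajectoryRecord] = []
    warned = False
    for ev, group in zip(events, group_labels):
        if not ev.clusters or not ev.clusters[0] or not ev.clusters[-1]:
            raise ValueError("event lacks qualifying clusters at its endpoints")
        endpoints = []
        for centroid in (ev.first_centroid, ev.last_centroid):
            r = int(round(centroid[0]))
            c = int(round(centroid[1]))
            r = min(max(r, 0), mask.shape[0] - 1)
            c = min(max(c, 0), mask.shape[1] - 1)
            if mask.labels[r, c] == 0 and not warned:
                warnings.warn("cluster centroid on background; assigned "
                              "nearest region", stacklevel=2)
                warned = True
            endpoints.append(int(lookup[r, c]))
        origin, destination = endpoints
        records.append(TrajectoryRecord(
            event_start=ev.start, origin=origin, destination=destination,
            displacement=(ev.last_centroid[0] - ev.first_centroid[0],
                          ev.last_centroid[1] - ev.first_centroid[1]),
            loop=origin == destination, group=str(group)))
    rows = []
    frame = pd.DataFrame([{"group": r.group, "origin": r.origin,
                           "destination": r.destination} for r in records])
    if len(frame):
        counts = frame.value_counts(["group", "origin", "destination"])
        for (group, origin, destination), count in counts.items():
            total = int((frame["group"] == group).sum())
            rows.append({"group": group,
                         "origin": REGION_LABELS.get(origin, str(origin)),
                         "destination": REGION_LABELS.get(destination,
                                                          str(destination)),
                         "count": int(count), "rate": count / total})
    table = pd.DataFrame(rows, columns=["group", "origin", "destination",
                                        "count", "rate"])
    return TrajectorySummary(records=records, table=table)
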