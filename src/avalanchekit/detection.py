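"""Avalanche detection on z-scored voltage-imaging sequences.

The detection chain follows the point-process convention used across the
neuronal-avalanche literature:

1. :func:`binarize_transitions` — a pixel is flagged at the instants its
   z-scored signal crosses a +3 s.d. threshold *from below*; while the
   signal stays above threshold no further flags are emitted.  Keeping only
   first crossings avoids double-counting pixels and tracks the activity
   wavefront rather than the already-activated area.
2. :func:`label_frames` — a frame *qualifies* if it contains a connected
   cluster of at least ``min_cluster_px`` flagged pixels (8-connectivity by
   default).  A frame is labeled *avalanche* when it and its two preceding
   and two following frames all qualify, and *quiescence* when it and the
   same context are all free of qualifying clusters; anything else —
   including the unjudgeable first/last context frames — is *excluded*.
   With the defaults this enforces the canonical minima: 100 ms duration
   and 50 pixels total size per avalanche.
3. :func:`extract_avalanches` — maximal runs of qualifying frames that
   contain at least one avalanche-labeled frame become
   :class:`AvalancheEvent` records (temporal contiguity of clusters is the
   only propagation condition).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .preprocess import ImageSequence

__all__ = [
    "AVALANCHE",
    "QUIESCENCE",
    "EXCLUDED",
    "PointProcessStack",
    "FrameLabeling",
    "AvalancheEvent",
    "binarize_transitions",
    "label_frames",
    "extract_avalanches",
    "events_to_dataframe",
]

AVALANCHE = 1
QUIESCENCE = 0
EXCLUDED = -1

_STRUCTURES = {
    8: np.ones((3, 3), dtype=int),
    4: ndimage.generate_binary_structure(2, 1),
}


@dataclass
class PointProcessStack:
    """Binary stack of per-pixel up-state transition flags."""

    flags: np.ndarray               # (frames, rows, cols) of {0, 1}
    threshold_sd: float = 3.0
    frame_interval_ms: float = 20.0

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags)
        if self.flags.ndim != 3:
            raise ValueError("flags must be (frames, rows, cols)")
        if not np.isin(self.flags, (0, 1)).all():
            raise ValueError("flags must be binary")
        self.flags = self.flags.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.flags.shape[0]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.flags)

    @classmethod
    def from_tiff(cls, path, threshold_sd: float = 3.0,
                  frame_interval_ms: float = 20.0) -> "PointProcessStack":
        return cls(tifffile.imread(path), threshold_sd, frame_interval_ms)


@dataclass
class FrameLabeling:
    """Per-frame avalanche/quiescence/excluded labels plus the qualifying map."""

    labels: np.ndarray              # per-frame {AVALANCHE, QUIESCENCE, EXCLUDED}
    qualifying: np.ndarray          # per-frame bool: has a qualifying cluster
    min_cluster_px: int = 10
    context_frames: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.qualifying = np.asarray(self.qualifying, dtype=bool)
        if self.labels.shape != self.qualifying.shape:
            raise ValueError("labels and qualifying must align")

    def frames_with(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.labels.size),
                             "label": self.labels,
                             "qualifying": self.qualifying.astype(int)})


@dataclass
class AvalancheEvent:
    """One avalanche: a maximal run of qualifying frames.

    ``start``/``end`` index frames as a half-open interval.  ``clusters``
    holds, per frame of the run, the flat pixel indices of every qualifying
    cluster.  ``size`` is the total flagged-pixel count over those clusters
    and ``duration_ms`` the run length times the frame interval.
    """

    start: int
    end: int
    clusters: list = field(default_factory=list)   # per frame: list of index arrays
    size: int = 0
    duration_ms: float = 0.0
    first_centroid: tuple[float, float] = (0.0, 0.0)
    last_centroid: tuple[float, float] = (0.0, 0.0)

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def binarize_transitions(seq, threshold_sd: float = 3.0) -> PointProcessStack:
    """Flag below-to-above threshold crossings per pixel.

    ``flags[t] = 1`` iff the pixel value at ``t`` is at or above the
    threshold while the value at ``t - 1`` was below it.  Frame 0 is never
    flagged (no preceding sample to establish a crossing).  Accepts an
    :class:`~avalanchekit.preprocess.ImageSequence` or a raw array; warns if
    the input does not look z-scored.
    """
    if isinstance(seq, ImageSequence):
        data = seq.data
        valid = seq.valid_mask
        interval = seq.frame_interval_ms
    else:
        data = np.asarray(seq, dtype=float)
        valid = np.ones(data.shape[1:], dtype=bool)
        interval = 20.0
    if valid.any():
        max_mean = np.abs(data[:, valid].mean(axis=0)).max()
        if max_mean > 0.1:
            warnings.warn(
                f"input does not look z-scored (max |pixel mean| = {max_mean:.3f})",
                stacklevel=2)
    flags = np.zeros(data.shape, dtype=np.uint8)
    flags[1:] = (data[1:] >= threshold_sd) & (data[:-1] < threshold_sd)
    flags[:, ~valid] = 0
    return PointProcessStack(flags, threshold_sd=threshold_sd,
                             frame_interval_ms=interval)


def _qualifying_clusters(frame: np.ndarray, min_cluster_px: int,
                         structure: np.ndarray,
                         strict: bool) -> list[np.ndarray]:
    """Flat pixel indices of each connected cluster meeting the size criterion."""
    labeled, n = ndimage.label(frame, structure=structure)
    if n == 0:
        return []
    sizes = np.bincount(labeled.ravel())[1:]
    keep = sizes > min_cluster_px if strict else sizes >= min_cluster_px
    out = []
    flat = labeled.ravel()
    for comp in np.nonzero(keep)[0] + 1:
        out.append(np.nonzero(flat == comp)[0])
    return out


def label_frames(pp: PointProcessStack, min_cluster_px: int = 10,
                 context_frames: int = 2, connectivity: int = 8,
                 strict: bool = False) -> FrameLabeling:
    """Label each frame avalanche / quiescence / excluded.

    A frame qualifies when some connected component of its flags reaches
    ``min_cluster_px`` pixels (``strict=True`` demands strictly more).  A
    frame is labeled avalanche when it and ``context_frames`` neighbors on
    each side all qualify; quiescence when it and the same neighbors are all
    non-qualifying; otherwise excluded.  The first and last
    ``context_frames`` frames are always excluded.
    """
    structure = _STRUCTURES[connectivity]
    T = pp.n_frames
    qual = np.zeros(T, dtype=bool)
    for t in range(T):
        qual[t] = bool(_qualifying_clusters(pp.flags[t], min_cluster_px,
                                            structure, strict))
    labels = np.full(T, EXCLUDED, dtype=np.int8)
    c = context_frames
    for t in range(c, T - c):
        window = qual[t - c:t + c + 1]
        if window.all():
            labels[t] = AVALANCHE
        elif not window.any():
            labels[t] = QUIESCENCE
    return FrameLabeling(labels=labels, qualifying=qual,
                         min_cluster_px=min_cluster_px,
                         context_frames=context_frames)


def extract_avalanches(pp: PointProcessStack, labeling: FrameLabeling,
                       connectivity: int = 8,
                       strict: bool = False) -> list[AvalancheEvent]:
    """Cut maximal qualifying runs containing an avalanche-labeled frame.

    Event boundaries follow runs of *qualifying* frames (not of
    avalanche-labeled frames): the two-frame context rule would otherwise
    erode each event's extent by two frames on either side.  Runs without
    any avalanche-labeled frame fail the duration minimum and are excluded
    in their entirety.
    """
    structure = _STRUCTURES[connectivity]
    qual = labeling.qualifying
    T = pp.n_frames
    events: list[AvalancheEvent] = []
    t = 0
    while t < T:
        if not qual[t]:
            t += 1
            continue
        start = t
        while t < T and qual[t]:
            t += 1
        end = t
        if not np.any(labeling.labels[start:end] == AVALANCHE):
            continue
        clusters = [
            _qualifying_clusters(pp.flags[f], labeling.min_cluster_px,
                                 structure, strict)
            for f in range(start, end)
        ]
        size = int(sum(idx.size for frame in clusters for idx in frame))
        W = pp.flags.shape[2]

        def _largest_centroid(frame_clusters):
            largest = max(frame_clusters, key=lambda a: a.size)
            return (float(np.mean(largest // W)), float(np.mean(largest % W)))

        events.append(AvalancheEvent(
            start=start, end=end, clusters=clusters, size=size,
            duration_ms=(end - start) * pp.frame_interval_ms,
            first_centroid=_largest_centroid(clusters[0]),
            last_centroid=_largest_centroid(clusters[-1])))
    return events


def events_to_dataframe(events: list[AvalancheEvent]) -> pd.DataFrame:
    """Tabulate events (one row each; centroid coordinates are row, col)."""
    return pd.DataFrame([
        {"start": e.start, "end": e.end, "n_frames": e.n_frames,
         "size_px": e.size, "duration_ms": e.duration_ms,
         "first_centroid_row": e.first_centroid[0],
         "first_centroid_col": e.first_centroid[1],
         "last_centroid_row": e.last_centroid[0],
         "last_centroid_col": e.last_centroid[1]}
        for e in events
    ], columns=["start", "end", "n_frames", "size_px", "duration_ms",
                "first_centroid_row", "first_centroid_col",
                "last_centroid_row", "last_centroid_col"])


def events_to_json(events: list[AvalancheEvent], path) -> None:
    payload = [
        {"start": int(e.start), "end": int(e.end), "size_px": int(e.size),
         "duration_ms": float(e.duration_ms),
         "first_centroid": list(map(float, e.first_centroid)),
         "last_centroid": list(map(float, e.last_centroid)),
         "clusters": [[np.asarray(c).astype(int).tolist() for c in frame]
                      for frame in e.clusters]}
        for e in events
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)
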