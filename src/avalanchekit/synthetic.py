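"""Synthetic widefield voltage-imaging sequences with planted avalanches.

Real recordings of this kind image one cortical hemisphere at ~50 Hz with a
genetically encoded voltage indicator; spontaneous activity alternates
between quiescent stretches of temporally correlated noise and sparse
cascades ("neuronal avalanches") in which a connected cluster of pixels
transitions to the up-state and the activation front travels across cortical
regions.  This module emulates exactly those statistics so the downstream
detection, classification and mapping stages can be exercised and tested
without the original recordings:

* a label map partitioning the pixel grid into four cortical regions
  (motor, somatosensory, visual, retrosplenial);
* per-pixel Gaussian AR(1) background noise (band-passed optical data are
  temporally correlated; AR(1) is the simplest process with that property);
* propagating events: a disc-shaped wavefront of configurable pixel count,
  elevated by a configurable amplitude (in noise-s.d. units), whose center
  moves linearly from an origin region to a target region over the event
  duration.  Because only the moving front is elevated, each frame
  contributes fresh below-to-above threshold crossings — the signal shape
  the point-process detector assumes.

Every simulation also returns a :class:`GroundTruth` log so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .preprocess import ImageSequence

__all__ = [
    "REGION_LABELS",
    "RegionMask",
    "SimulationConfig",
    "GroundTruthEvent",
    "GroundTruth",
    "SizingError",
    "PlacementError",
    "generate_region_masks",
    "simulate_sequence",
    "awake_config",
    "anesthetized_config",
]

#: Region label coding used throughout the package (0 is background).
REGION_LABELS = {1: "motor", 2: "somatosensory", 3: "visual", 4: "retrosplenial"}
REGION_IDS = {name: label for label, name in REGION_LABELS.items()}

MIN_REGION_PIXELS = 200
MIN_GRID = 40


class SizingError(ValueError):
    """A grid or region is too small to satisfy the region invariants."""


class PlacementError(ValueError):
    """Requested events cannot be placed under the non-overlap constraints."""


@dataclass
class RegionMask:
    """Integer label map of cortical regions.

    ``labels`` is a ``rows x cols`` integer array with values in
    {0 background, 1 motor, 2 somatosensory, 3 visual, 4 retrosplenial}.
    Regions are pairwise disjoint by construction; :meth:`validate` checks
    connectedness and the minimum-size invariant (>= 200 pixels per region,
    so 10x10 entropy windows and 2-pixel erosion stay meaningful).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_pixels(self, label: int) -> np.ndarray:
        """Boolean map of the pixels carrying ``label``."""
        return self.labels == label

    def centroid(self, label: int) -> np.ndarray:
        rows, cols = np.nonzero(self.labels == label)
        if rows.size == 0:
            raise ValueError(f"region {label} is empty")
        return np.array([rows.mean(), cols.mean()])

    def validate(self) -> None:
        from scipy import ndimage

        for label in REGION_LABELS:
            region = self.labels == label
            n = int(region.sum())
            if n < MIN_REGION_PIXELS:
                raise SizingError(
                    f"region {label} has {n} pixels (< {MIN_REGION_PIXELS})")
            _, n_comp = ndimage.label(region, structure=np.ones((3, 3)))
            if n_comp != 1:
                raise ValueError(f"region {label} is not connected")

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.int32))

    @classmethod
    def from_tiff(cls, path) -> "RegionMask":
        return cls(tifffile.imread(path))


def generate_region_masks(dims: tuple[int, int], seed: int) -> RegionMask:
    """Partition a pixel grid into 4 labeled cortical regions.

    The grid is tiled into four rectangular quadrants whose dividing lines
    are jittered by up to 10% of each dimension, seeded for determinism.
    The quadrants cover the whole grid, so every simulated wavefront path
    between region centroids stays inside labeled cortex.

    Raises
    ------
    SizingError
        If either dimension is below 40 pixels (regions could fall under
        the 200-pixel minimum).
    """
    rows, cols = dims
    if rows < MIN_GRID or cols < MIN_GRID:
        raise SizingError(f"grid {rows}x{cols} too small; need >= {MIN_GRID} per side")
    rng = np.random.default_rng(seed)
    jr = max(1, rows // 10)
    jc = max(1, cols // 10)
    r_split = rows // 2 + int(rng.integers(-jr, jr + 1))
    c_split = cols // 2 + int(rng.integers(-jc, jc + 1))
    labels = np.zeros((rows, cols), dtype=np.int32)
    labels[:r_split, :c_split] = 1   # motor
    labels[:r_split, c_split:] = 2   # somatosensory
    labels[r_split:, :c_split] = 3   # visual
    labels[r_split:, c_split:] = 4   # retrosplenial
    mask = RegionMask(labels)
    mask.validate()
    return mask


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

#: Default routing: dominant visual-to-motor cascades plus motor loops, the
#: two trajectory classes most prominent in this kind of data, with minor
#: somatosensory-to-motor and retrosplenial-loop traffic.
DEFAULT_ROUTES = (
    ((3, 1), 0.5),
    ((1, 1), 0.2),
    ((2, 1), 0.15),
    ((4, 4), 0.15),
)


@dataclass
class SimulationConfig:
    """Parameters of a synthetic voltage-imaging run.

    Attributes
    ----------
    rows, cols
        Pixel grid dimensions.
    n_frames
        Number of frames to simulate.
    frame_interval_ms
        Frame interval (20 ms = 50 Hz nominal acquisition).
    noise_sd
        Stationary standard deviation of the per-pixel background noise.
    ar_coeff
        AR(1) coefficient of the temporal noise correlation (0 = white).
    event_rate
        Events per 1000 frames.
    amplitude_sd
        Event elevation in units of ``noise_sd``; must exceed the +3 s.d.
        detection threshold.
    cluster_px
        Minimum pixel count of the per-frame wavefront cluster (> 10 so
        clusters qualify under the detector's default criterion).
    duration_frames
        Event duration in frames (>= 5, the detector's implied minimum).
    routes
        ``(((origin_label, target_label), probability), ...)`` propagation
        routes; probabilities are normalized.
    amplitude_jitter_sd
        S.d. of per-event amplitude jitter (awake-like variability).
    allow_concurrent
        Permit events to overlap in time (awake-like preset); the default
        (False) keeps events separated by ``min_gap_frames``.
    min_gap_frames
        Minimum quiescent gap between consecutive events (must exceed the
        detector's 2-frame context window).
    seed
        Seed for all randomness in the simulation.
    """

    rows: int = 120
    cols: int = 120
    n_frames: int = 2000
    frame_interval_ms: float = 20.0
    noise_sd: float = 1.0
    ar_coeff: float = 0.5
    event_rate: float = 10.0
    amplitude_sd: float = 5.0
    cluster_px: int = 12
    duration_frames: int = 6
    routes: tuple = DEFAULT_ROUTES
    amplitude_jitter_sd: float = 0.0
    allow_concurrent: bool = False
    min_gap_frames: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.amplitude_sd <= 3:
            raise ValueError("event amplitude must exceed the 3 s.d. threshold")
        if self.duration_frames < 5:
            raise ValueError("event duration must be >= 5 frames")
        if self.cluster_px <= 10:
            raise ValueError("cluster size must exceed 10 pixels")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_json(self, path) -> None:
        payload = {k: (list(v) if k == "routes" else v)
                   for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = json.load(fh)
        if "routes" in payload:
            payload["routes"] = tuple(
                ((int(o), int(t)), float(p)) for (o, t), p in payload["routes"])
        return cls(**payload)


def awake_config(**overrides) -> SimulationConfig:
    """Awake-like regime: frequent, small, jittered, possibly concurrent events."""
    base = dict(event_rate=20.0, cluster_px=12, duration_frames=5,
                amplitude_jitter_sd=0.8, allow_concurrent=True)
    base.update(overrides)
    return SimulationConfig(**base)


def anesthetized_config(**overrides) -> SimulationConfig:
    """Anesthetized-like regime: sparse, large, stereotyped events."""
    base = dict(event_rate=6.0, cluster_px=24, duration_frames=8,
                amplitude_jitter_sd=0.0, allow_concurrent=False)
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEvent:
    """One planted cascade: frame span, route, and per-frame active pixels."""

    start: int                      # first frame (inclusive)
    end: int                        # one past the last frame (half-open)
    origin: int                     # region label
    target: int                     # region label
    frames: list = field(default_factory=list)  # per-frame flat pixel indices

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Event log of a simulation."""

    events: list
    shape: tuple[int, int]

    def validate(self, mask: RegionMask, allow_concurrent: bool = False) -> None:
        spans = sorted((e.start, e.end) for e in self.events)
        if not allow_concurrent:
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError("ground-truth events overlap in time")
        flat_labels = mask.labels.ravel()
        for ev in self.events:
            for px in ev.frames:
                if np.any(flat_labels[px] == 0):
                    raise ValueError("active pixel outside labeled regions")

    def to_json(self, path) -> None:
        payload = {
            "shape": list(self.shape),
            "events": [
                {"start": int(e.start), "end": int(e.end),
                 "origin": int(e.origin), "target": int(e.target),
                 "frames": [np.asarray(f).astype(int).tolist() for f in e.frames]}
                for e in self.events
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        events = [GroundTruthEvent(
            start=e["start"], end=e["end"], origin=e["origin"],
            target=e["target"],
            frames=[np.asarray(f, dtype=np.int64) for f in e["frames"]])
            for e in payload["events"]]
        return cls(events=events, shape=tuple(payload["shape"]))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _disc_offsets(radius: int) -> np.ndarray:
    """Row/col offsets of a filled disc of the given integer radius."""
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    keep = rr ** 2 + cc ** 2 <= radius ** 2
    return np.stack([rr[keep], cc[keep]], axis=1)


def _radius_for(cluster_px: int) -> int:
    """Disc radius whose pixel count comfortably exceeds ``cluster_px``.

    One radius step of headroom keeps the cluster above the configured
    minimum even when a few pixels fall below the detection threshold
    because of unlucky background noise at the event frame.
    """
    radius = 1
    while _disc_offsets(radius).shape[0] < cluster_px:
        radius += 1
    return radius + 1


def _min_step(radius: int, cluster_px: int) -> int:
    """Smallest per-frame center displacement whose fresh (newly covered)
    pixel count stays above ``cluster_px`` with margin."""
    disc = {tuple(p) for p in _disc_offsets(radius)}
    for step in range(1, 2 * radius + 3):
        fresh = len({(r + step, c) for r, c in disc} - disc)
        if fresh >= cluster_px + 6:
            return step
    return 2 * radius + 2


def _place_starts(rng: np.random.Generator, n_events: int, n_frames: int,
                  duration: int, gap: int, concurrent: bool) -> list[int]:
    """Sample non-overlapping (unless concurrent) event start frames."""
    lo, hi = gap, n_frames - duration - gap
    if hi <= lo:
        raise PlacementError("sequence too short for any event")
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_events:
        attempts += 1
        if attempts > 500 * max(n_events, 1):
            raise PlacementError(
                f"could not place {n_events} events of duration {duration} "
                f"with gap {gap} in {n_frames} frames")
        cand = int(rng.integers(lo, hi + 1))
        if concurrent or all(abs(cand - s) >= duration + gap for s in starts):
            starts.append(cand)
    return sorted(starts)


def _event_path(mask: RegionMask, origin: int, target: int, duration: int,
                radius: int, step: int) -> np.ndarray:
    """Disc-center positions for one event, spaced so each frame's disc
    covers enough fresh pixels to yield a qualifying set of new threshold
    crossings."""
    rows, cols = mask.shape
    length = step * (duration - 1)
    if origin == target:
        center = mask.centroid(origin)
        rr, cc = np.nonzero(mask.labels == origin)
        span = np.array([rr.max() - rr.min(), cc.max() - cc.min()], dtype=float)
        direction = span / np.linalg.norm(span)
    else:
        p0, p1 = mask.centroid(origin), mask.centroid(target)
        center = (p0 + p1) / 2.0
        direction = p1 - p0
        norm = np.linalg.norm(direction)
        if norm == 0:
            direction = np.array([1.0, 0.0])
        else:
            direction = direction / norm
    half = direction * length / 2.0
    positions = np.linspace(center - half, center + half, duration)
    positions[:, 0] = np.clip(positions[:, 0], radius, rows - 1 - radius)
    positions[:, 1] = np.clip(positions[:, 1], radius, cols - 1 - radius)
    return positions


def simulate_sequence(config: SimulationConfig,
                      mask: RegionMask) -> tuple[ImageSequence, GroundTruth]:
    """Simulate a voltage-imaging sequence with planted cascades.

    Background pixels follow stationary Gaussian AR(1) noise with s.d.
    ``config.noise_sd``.  Each event elevates a moving disc-shaped cluster
    of at least ``config.cluster_px`` pixels by
    ``config.amplitude_sd * config.noise_sd``, the disc center traveling
    from the origin-region centroid toward the target-region centroid over
    ``config.duration_frames`` frames.  Noise and event placement use
    independent child generators of ``config.seed``, so the noise field is
    reproducible across different event settings at the same seed.

    Returns the sequence and a matching :class:`GroundTruth` log.

    Raises
    ------
    PlacementError
        If the requested event rate cannot be honored without overlap, or
        the wavefront geometry cannot deliver the configured per-frame
        cluster size.
    """
    config.validate()
    if mask.shape != (config.rows, config.cols):
        raise ValueError("mask shape does not match configured grid")
    noise_seq, event_seq = np.random.SeedSequence(config.seed).spawn(2)
    rng_noise = np.random.default_rng(noise_seq)
    rng_events = np.random.default_rng(event_seq)

    T, H, W = config.n_frames, config.rows, config.cols
    data = np.empty((T, H, W), dtype=float)
    a = config.ar_coeff
    innovation_sd = config.noise_sd * np.sqrt(1.0 - a ** 2)
    data[0] = config.noise_sd * rng_noise.standard_normal((H, W))
    for t in range(1, T):
        data[t] = a * data[t - 1] + innovation_sd * rng_noise.standard_normal((H, W))

    n_events = int(round(config.event_rate * T / 1000.0))
    events: list[GroundTruthEvent] = []
    if n_events > 0:
        starts = _place_starts(rng_events, n_events, T, config.duration_frames,
                               config.min_gap_frames, config.allow_concurrent)
        route_pairs = [pair for pair, _ in config.routes]
        probs = np.array([p for _, p in config.routes], dtype=float)
        probs = probs / probs.sum()
        radius = _radius_for(config.cluster_px)
        step = _min_step(radius, config.cluster_px)
        flat_labels = mask.labels.ravel()
        for start in starts:
            origin, target = route_pairs[int(rng_events.choice(len(route_pairs),
                                                               p=probs))]
            amp = config.amplitude_sd
            if config.amplitude_jitter_sd > 0:
                amp = max(3.5, amp + config.amplitude_jitter_sd
                          * rng_events.standard_normal())
            positions = _event_path(mask, origin, target,
                                    config.duration_frames, radius, step)
            offsets = _disc_offsets(radius)
            frames = []
            prev: set[int] = set()
            for i, pos in enumerate(positions):
                pix = np.round(pos).astype(int) + offsets
                flat = pix[:, 0] * W + pix[:, 1]
                flat = flat[flat_labels[flat] > 0]
                fresh = set(flat.tolist()) - prev
                if len(fresh) < config.cluster_px:
                    raise PlacementError(
                        "wavefront geometry yields fewer fresh pixels than "
                        f"cluster_px at event frame {i}; reduce duration or "
                        "cluster size for this grid")
                data[start + i].ravel()[flat] += amp * config.noise_sd
                frames.append(np.sort(flat))
                prev = set(flat.tolist())
            events.append(GroundTruthEvent(
                start=start, end=start + config.duration_frames,
                origin=origin, target=target, frames=frames))

    seq = ImageSequence(data, frame_interval_ms=config.frame_interval_ms)
    truth = GroundTruth(events=events, shape=(H, W))
    truth.validate(mask, allow_concurrent=config.allow_concurrent)
    return seq, truth
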