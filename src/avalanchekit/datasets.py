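"""Balanced, region-restricted training sets for avalanche classification.

From a labeled sequence this module builds the example matrices the
classifiers consume:

* :func:`erode_region_masks` — shrink each cortical region by a 2-pixel
  morphological erosion so the networks learn only from intra-cortical
  pixels.
* :func:`make_balanced_splits` — draw equal numbers of avalanche and
  quiescence frames (the minority class governs) and partition them
  80/10/10 into train/validation/test, seeded and without replacement.
* :func:`assemble_examples` — gather each selected frame's region pixels
  into a feature vector (region blocks in label order), optionally pairing
  frame T1 with its immediate predecessor T2 for the dual-frame
  architectures, and min-max normalize to [0, 1] using training-partition
  statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detection import AVALANCHE, QUIESCENCE, FrameLabeling
from .preprocess import ImageSequence
from .synthetic import REGION_LABELS, RegionMask, SizingError

__all__ = [
    "SplitIndices",
    "FeatureLayout",
    "DatasetSplit",
    "erode_region_masks",
    "make_balanced_splits",
    "assemble_examples",
]


def erode_region_masks(mask: RegionMask, depth_px: int = 2,
                       structure: np.ndarray | None = None) -> RegionMask:
    """Morphologically erode each labeled region by ``depth_px`` pixels.

    Uses a 3x3 square structuring element, so a 10x10 square region eroded
    by 2 becomes 6x6.  Raises :class:`SizingError` if a region vanishes and
    ``ValueError`` if erosion splits a region into multiple components.
    """
    if depth_px < 0:
        raise ValueError("depth_px must be >= 0")
    if depth_px == 0:
        return RegionMask(mask.labels.copy())
    if structure is None:
        structure = np.ones((3, 3), dtype=bool)
    out = np.zeros_like(mask.labels)
    for label in REGION_LABELS:
        region = mask.labels == label
        if not region.any():
            continue
        eroded = ndimage.binary_erosion(region, structure=structure,
                                        iterations=depth_px)
        if not eroded.any():
            raise SizingError(f"region {label} vanishes under {depth_px}-pixel erosion")
        _, n_comp = ndimage.label(eroded, structure=np.ones((3, 3)))
        if n_comp != 1:
            raise ValueError(f"erosion disconnects region {label}")
        out[eroded] = label
    return RegionMask(out)


@dataclass
class SplitIndices:
    """Frame indices and labels of the three balanced partitions."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    train_labels: np.ndarray
    val_labels: np.ndarray
    test_labels: np.ndarray
    seed: int = 0
    fractions: tuple = (0.8, 0.1, 0.1)

    def partition(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return {"train": (self.train, self.train_labels),
                "val": (self.val, self.val_labels),
                "test": (self.test, self.test_labels)}[name]


def _frame_label_array(labeling) -> np.ndarray:
    if isinstance(labeling, FrameLabeling):
        return labeling.labels
    return np.asarray(labeling)


def make_balanced_splits(labeling, fractions: tuple = (0.8, 0.1, 0.1),
                         seed: int = 0) -> SplitIndices:
    """Class-balanced train/val/test frame selection.

    The minority class count ``m`` governs: each class contributes
    ``floor(f_train * m)`` / ``floor(f_val * m)`` frames to train/val and
    the remainder (of the ``m`` drawn) to test, sampled without replacement
    and deterministically per seed.  Partitions are disjoint and exactly
    balanced.

    Raises
    ------
    ValueError
        If a class is empty, fractions are invalid, or some partition would
        receive no frame of one class.
    """
    labels = _frame_label_array(labeling)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 \
            or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative values summing to 1")
    ava = np.nonzero(labels == AVALANCHE)[0]
    qui = np.nonzero(labels == QUIESCENCE)[0]
    if ava.size == 0:
        raise ValueError("no avalanche frames available")
    if qui.size == 0:
        raise ValueError("no quiescence frames available")
    m = min(ava.size, qui.size)
    n_train = int(np.floor(fractions[0] * m))
    n_val = int(np.floor(fractions[1] * m))
    n_test = m - n_train - n_val
    for name, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        if n == 0:
            raise ValueError(f"partition '{name}' would receive no frames; "
                             f"minority class has only {m} frames")
    rng = np.random.default_rng(seed)
    parts = {name: ([], []) for name in ("train", "val", "test")}
    for cls_label, pool in ((AVALANCHE, ava), (QUIESCENCE, qui)):
        chosen = rng.permutation(pool)[:m]
        chunks = {"train": chosen[:n_train],
                  "val": chosen[n_train:n_train + n_val],
                  "test": chosen[n_train + n_val:]}
        for name, idx in chunks.items():
            parts[name][0].append(idx)
            parts[name][1].append(np.full(idx.size, cls_label, dtype=np.int8))

    def _cat(name):
        idx = np.concatenate(parts[name][0])
        lab = np.concatenate(parts[name][1])
        order = np.argsort(idx, kind="stable")
        return idx[order], lab[order]

    (tr, trl), (va, val_), (te, tel) = _cat("train"), _cat("val"), _cat("test")
    return SplitIndices(train=tr, val=va, test=te, train_labels=trl,
                        val_labels=val_, test_labels=tel, seed=seed,
                        fractions=tuple(fractions))


@dataclass
class FeatureLayout:
    """Region-block ordering of features: which pixel feeds which feature.

    ``region_order`` lists region labels in feature order; ``pixel_indices``
    holds, per region, the flat pixel indices (row-major within the region)
    of the frame grid.  For dual-frame examples the whole layout repeats:
    first all T1 blocks, then all T2 blocks.
    """

    region_order: tuple
    pixel_indices: dict                     # label -> flat indices
    frame_shape: tuple[int, int]

    @property
    def region_sizes(self) -> tuple:
        return tuple(self.pixel_indices[r].size for r in self.region_order)

    @property
    def n_features(self) -> int:
        return int(sum(self.region_sizes))

    def region_slices(self) -> dict:
        slices, offset = {}, 0
        for r in self.region_order:
            n = self.pixel_indices[r].size
            slices[r] = slice(offset, offset + n)
            offset += n
        return slices

    def gather(self, frame: np.ndarray) -> np.ndarray:
        """Frame (2-D) -> feature vector in region-block order."""
        flat = frame.ravel()
        return np.concatenate([flat[self.pixel_indices[r]]
                               for r in self.region_order])

    def scatter(self, features: np.ndarray,
                fill: float = 0.0) -> np.ndarray:
        """Feature vector -> 2-D map (pixels outside regions set to ``fill``)."""
        out = np.full(self.frame_shape, fill, dtype=float)
        flat = out.ravel()
        for r, sl in self.region_slices().items():
            flat[self.pixel_indices[r]] = features[sl]
        return out

    @classmethod
    def from_mask(cls, mask: RegionMask,
                  region_order: tuple | None = None) -> "FeatureLayout":
        order = tuple(region_order) if region_order else tuple(sorted(REGION_LABELS))
        order = tuple(r for r in order if (mask.labels == r).any())
        pixel_indices = {r: np.nonzero((mask.labels == r).ravel())[0]
                         for r in order}
        return cls(region_order=order, pixel_indices=pixel_indices,
                   frame_shape=mask.shape)


@dataclass
class DatasetSplit:
    """Assembled example matrices for one single- or dual-frame dataset."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    layout: FeatureLayout
    mode: str                                # "single" | "dual"
    feature_min: np.ndarray = None
    feature_range: np.ndarray = None
    frame_indices: dict = field(default_factory=dict)  # partition -> frames used

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]

    def partition(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return {"train": (self.X_train, self.y_train),
                "val": (self.X_val, self.y_val),
                "test": (self.X_test, self.y_test)}[name]


def assemble_examples(seq: ImageSequence, mask: RegionMask,
                      split: SplitIndices, mode: str = "single",
                      region_order: tuple | None = None) -> DatasetSplit:
    """Build normalized example matrices from selected frames.

    Features are region-block-ordered pixel values of frame T1; in dual
    mode the block layout repeats for the immediately preceding frame T2
    (an example's label is that of T1).  Frame 0 cannot supply a T2
    predecessor and is dropped with a warning if selected in dual mode.
    Min-max statistics come from the training partition alone and are
    applied to every partition; values are clipped to [0, 1].  Training
    features with zero range normalize to 0 (with a warning).
    """
    if mode not in ("single", "dual"):
        raise ValueError("mode must be 'single' or 'dual'")
    layout = FeatureLayout.from_mask(mask, region_order)

    def _gather_frames(indices, labels):
        keep = indices >= (1 if mode == "dual" else 0)
        if not keep.all():
            warnings.warn("frame 0 has no predecessor; dropped from dual-mode "
                          "selection", stacklevel=2)
        idx, lab = indices[keep], labels[keep]
        rows = []
        for t in idx:
            t1 = layout.gather(seq.data[t])
            if mode == "dual":
                rows.append(np.concatenate([t1, layout.gather(seq.data[t - 1])]))
            else:
                rows.append(t1)
        X = np.asarray(rows, dtype=float) if rows else \
            np.empty((0, layout.n_features * (2 if mode == "dual" else 1)))
        return X, lab.astype(np.int8), idx

    X_tr, y_tr, f_tr = _gather_frames(*split.partition("train"))
    X_va, y_va, f_va = _gather_frames(*split.partition("val"))
    X_te, y_te, f_te = _gather_frames(*split.partition("test"))

    fmin = X_tr.min(axis=0)
    frange = X_tr.max(axis=0) - fmin
    flat = frange == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant training feature(s) "
                      "normalized to 0", stacklevel=2)
    safe = np.where(flat, 1.0, frange)

    def _norm(X):
        if X.size == 0:
            return X
        out = (X - fmin) / safe
        out[:, flat] = 0.0
        return np.clip(out, 0.0, 1.0)

    return DatasetSplit(
        X_train=_norm(X_tr), y_train=y_tr, X_val=_norm(X_va), y_val=y_va,
        X_test=_norm(X_te), y_test=y_te, layout=layout, mode=mode,
        feature_min=fmin, feature_range=frange,
        frame_indices={"train": f_tr, "val": f_va, "test": f_te})
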