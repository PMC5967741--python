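"""Clustering of hidden-layer activations and cortical intensity maps.

After training, test-set frames are pushed through a classifier and the
first hidden layer's activations (the RBM-initialized, region-grouped
layer shared by all seven architectures) are clustered with k-means++
(k = 4, best of 10 restarts by within-cluster sum of squared distances).
Each cluster is identified as an avalanche or quiescence type by the
majority true label of its members; the four clusters correspond to two
quiescence types (k1, k2) and two avalanche types (k3, k4).  Cluster
centroids are back-projected linearly — multiplied through the transposed
masked weight matrices back to the input layer — and scattered into pixel
space to display how each characteristic pattern is encoded over the
cortex.  Summing the z-scored frames that were correctly clustered gives
the matching cortical activity maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .datasets import FeatureLayout
from .nets import FFNNModel
from .preprocess import ImageSequence
from .synthetic import RegionMask

__all__ = [
    "ClusterResult",
    "IntensityMap",
    "cluster_hidden_activations",
    "assign_cluster_identity",
    "backproject_centroid",
    "cortical_activity_map",
    "normalize_intensity",
]


@dataclass
class ClusterResult:
    """k-means++ clustering of hidden activations."""

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float                          # within-cluster sum of squared distances
    restart_inertias: list = field(default_factory=list)
    identity: dict = field(default_factory=dict)   # cluster -> 0 (qui) / 1 (ava)


@dataclass
class IntensityMap:
    """A 2-D cortical intensity map with its normalization scope."""

    values: np.ndarray
    scope: str = "raw"                      # "raw" | "per-region" | "per-map"
    source: dict = field(default_factory=dict)


def cluster_hidden_activations(activations: np.ndarray, k: int = 4,
                               restarts: int = 10, seed: int = 0) -> ClusterResult:
    """Cluster activation vectors with k-means++ (squared Euclidean).

    Runs ``restarts`` independent initializations and keeps the model with
    the lowest total within-cluster sum of squared distances.
    """
    activations = np.asarray(activations, dtype=float)
    if activations.ndim != 2 or activations.shape[0] == 0:
        raise ValueError("activations must be a non-empty 2-D array")
    if k > activations.shape[0]:
        raise ValueError(f"k={k} exceeds example count {activations.shape[0]}")
    child_seeds = np.random.SeedSequence(int(seed)).generate_state(restarts)
    best, inertias = None, []
    for child in child_seeds:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    random_state=int(child) % (2 ** 32)).fit(activations)
        inertias.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    return ClusterResult(k=k, assignments=best.labels_,
                         centroids=best.cluster_centers_,
                         inertia=float(best.inertia_),
                         restart_inertias=inertias)


def assign_cluster_identity(result: ClusterResult,
                            true_labels: np.ndarray) -> dict:
    """Label each cluster avalanche (1) / quiescence (0) by majority vote.

    Stores the map on ``result.identity`` and returns it.  An exact 50/50
    cluster is labeled quiescence with a warning.  Use
    :func:`correctly_clustered` for the member-level agreement mask.
    """
    true_labels = np.asarray(true_labels)
    if true_labels.size != result.assignments.size:
        raise ValueError("one true label per clustered example required")
    identity = {}
    for c in range(result.k):
        members = true_labels[result.assignments == c]
        if members.size == 0:
            identity[c] = 0
            continue
        n_ava = int((members == 1).sum())
        n_qui = members.size - n_ava
        if n_ava == n_qui:
            warnings.warn(f"cluster {c} is exactly balanced; labeled "
                          "quiescence", stacklevel=2)
            identity[c] = 0
        else:
            identity[c] = int(n_ava > n_qui)
    result.identity = identity
    return identity


def correctly_clustered(result: ClusterResult,
                        true_labels: np.ndarray) -> np.ndarray:
    """Boolean mask of examples whose true label matches their cluster's identity."""
    if not result.identity:
        assign_cluster_identity(result, true_labels)
    ids = np.array([result.identity[c] for c in result.assignments])
    return ids == np.asarray(true_labels)


def backproject_centroid(centroid: np.ndarray, model: FFNNModel,
                         layout: FeatureLayout, hidden_layer: int = 1,
                         mask: RegionMask | None = None,
                         normalize: str = "per-region") -> dict:
    """Linearly back-project a hidden-layer centroid into pixel space.

    The centroid is multiplied through the transposes of the masked weight
    matrices from ``hidden_layer`` back to the input layer (masked entries
    are exactly zero, so a region-constrained unit cannot reach pixels
    outside its region), then scattered into the cortical map via the
    feature layout.  Dual-frame models yield ``"T1"`` and ``"T2"`` maps plus
    their ``"mean"``; single-frame models yield ``"T1"`` only.

    ``normalize`` ∈ {"per-region", "per-map", "raw"}; per-region rescales
    intensities to [0, 1] within each cortical region (requires ``mask``).
    """
    centroid = np.asarray(centroid, dtype=float).ravel()
    if centroid.size != model.spec.layer_sizes[hidden_layer]:
        raise ValueError(
            f"centroid size {centroid.size} does not match layer "
            f"{hidden_layer} size {model.spec.layer_sizes[hidden_layer]}")
    v = centroid
    for W in model.weights[hidden_layer - 1::-1]:
        v = v @ W
    n = layout.n_features
    blocks = {"T1": v[:n]}
    if model.spec.mode == "dual":
        blocks["T2"] = v[n:2 * n]
        blocks["mean"] = (blocks["T1"] + blocks["T2"]) / 2.0
    maps = {}
    for name, feats in blocks.items():
        raw = layout.scatter(feats)
        values = normalize_intensity(raw, mask, scope=normalize) \
            if normalize != "raw" else raw
        maps[name] = IntensityMap(values=values, scope=normalize,
                                  source={"slot": name,
                                          "arch": model.spec.arch_id})
    return maps


def normalize_intensity(values: np.ndarray, mask: RegionMask | None,
                        scope: str = "per-region") -> np.ndarray:
    """Min-max rescale intensities to [0, 1] per region or per map."""
    out = np.asarray(values, dtype=float).copy()
    if scope == "per-map":
        regions = [np.ones(out.shape, dtype=bool)] if mask is None \
            else [mask.labels > 0]
    elif scope == "per-region":
        if mask is None:
            raise ValueError("per-region normalization requires a region mask")
        labels = [l for l in np.unique(mask.labels) if l != 0]
        regions = [mask.labels == l for l in labels]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    covered = np.zeros(out.shape, dtype=bool)
    for sel in regions:
        vals = out[sel]
        if vals.size == 0:
            continue
        lo, hi = vals.min(), vals.max()
        out[sel] = 0.0 if hi == lo else (vals - lo) / (hi - lo)
        covered |= sel
    out[~covered] = 0.0
    return out


def cortical_activity_map(seq: ImageSequence, frame_indices,
                          mask: RegionMask | None = None,
                          normalize: str = "per-map") -> IntensityMap:
    """Sum z-scored frames over the given indices and min-max normalize.

    Typically called with the frames correctly clustered into one cluster
    type, giving the input-activity counterpart of a hidden-layer map.
    """
    frame_indices = np.asarray(frame_indices, dtype=int)
    if frame_indices.size == 0:
        raise ValueError("empty frame set")
    summed = seq.data[frame_indices].sum(axis=0)
    values = normalize_intensity(summed, mask, scope=normalize) \
        if normalize != "raw" else summed
    return IntensityMap(values=values, scope=normalize,
                        source={"n_frames": int(frame_indices.size)})
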