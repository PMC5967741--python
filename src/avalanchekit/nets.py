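"""Connection-masked RBMs and feed-forward avalanche classifiers.

Seven feed-forward architectures classify voltage-imaging frames as
avalanche (1) or quiescence (0).  Each is defined by binary connection
masks between consecutive layers that restrict which cortical regions and
time points may mix at each depth:

====  =====  ==========================================================
arch  input  constraint path (layer 2 is always grouped by region,
             and by time point for dual input)
====  =====  ==========================================================
1     single region-grouped hidden layer -> output ("s" at the output)
2     dual   region-and-time-grouped hidden layer -> output
3     dual   layer 3 mixes regions within each time point ("s"),
             output mixes time ("t")
4     single layer 3: one group per unordered region pair ("s(p)"),
             then fully mixed ("s")
5     dual   region pairs within each time point ("s(p)"), then output
             mixes space and time together ("s+t")
6     dual   region pairs per time ("s(p)"), layer 4 mixes space within
             each time ("s"), output mixes time ("t")
7     dual   layer 3: ordered cross-time region pairs ("s(p)+t"),
             then fully mixed ("s")
====  =====  ==========================================================

The first hidden layer carries 10 units per region per time point (40
single / 80 dual for four regions) and is pretrained as a restricted
Boltzmann machine under the same region mask; FFNN layer-1 weights are
initialized from the RBM.  Masks are enforced by zeroing masked weights at
the end of every training epoch, both for the RBM and the FFNN.  Hidden
units use the scaled hyperbolic tangent f(x) = 1.7159 tanh(2x/3); the
single output unit is logistic, trained with full-batch momentum gradient
descent on the squared error.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArchitectureSpec",
    "LesionJob",
    "RBMModel",
    "FFNNModel",
    "TrainingDivergedError",
    "build_architecture",
    "enumerate_model_grid",
    "train_rbm",
    "sweep_momentum",
    "init_ffnn_from_rbm",
    "train_ffnn",
    "evaluate",
    "SINGLE_ARCHS",
    "DUAL_ARCHS",
]

SINGLE_ARCHS = (1, 4)
DUAL_ARCHS = (2, 3, 5, 6, 7)

TANH_A = 1.7159
TANH_B = 2.0 / 3.0


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


# ---------------------------------------------------------------------------
# Architecture construction
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Layer sizes, per-layer-pair masks, and group bookkeeping.

    ``layer_groups[l]`` is a list of ``(key, width)`` pairs describing layer
    ``l``'s unit groups in order; keys are tuples such as ``("px", t, r)``
    for input pixels, ``(t, r)`` for first-hidden groups, ``("pair", t,
    (r1, r2))`` for region-pair groups, ``("xpair", (r1, r2))`` for
    cross-time pairs and ``("time", t)`` / ``("out",)`` for the rest.
    """

    arch_id: int
    mode: str                               # "single" | "dual"
    layer_sizes: list
    masks: list                             # per layer pair, (out x in) {0,1}
    annotations: list                       # constraint tag per layer pair
    layer_groups: list
    region_sizes: tuple
    hidden_per_region: int = 10
    group_width: int = 1

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    def group_slices(self, layer: int) -> dict:
        """Map group key -> unit slice within ``layer``."""
        slices, offset = {}, 0
        for key, width in self.layer_groups[layer]:
            slices[key] = slice(offset, offset + width)
            offset += width
        return slices


def _mask_from_groups(out_groups, in_groups, connected) -> np.ndarray:
    """Block mask: 1 where ``connected(out_key, in_key)``."""
    n_out = sum(w for _, w in out_groups)
    n_in = sum(w for _, w in in_groups)
    mask = np.zeros((n_out, n_in), dtype=np.uint8)
    r = 0
    for okey, ow in out_groups:
        c = 0
        for ikey, iw in in_groups:
            if connected(okey, ikey):
                mask[r:r + ow, c:c + iw] = 1
            c += iw
        r += ow
    return mask


def build_architecture(arch_id: int, region_sizes, mode: str | None = None,
                       group_width: int = 1,
                       hidden_per_region: int = 10) -> ArchitectureSpec:
    """Construct one of the seven constraint architectures.

    Parameters
    ----------
    arch_id
        Architecture number, 1–7.
    region_sizes
        Pixel count of each cortical region, in feature order.
    mode
        ``"single"`` or ``"dual"``; inferred from the architecture when
        omitted.  Architectures 1 and 4 are single-frame; 2, 3, 5, 6 and 7
        require dual-frame input.
    group_width
        Units per group in layers 3 and above (1 reproduces the illustrative
        three-region models: architectures 4, 5 and 7 then have 3, 6 and 9
        third-layer units on three regions).
    hidden_per_region
        First-hidden-layer units per region per time point (default 10, so
        40 single / 80 dual for four regions).
    """
    if arch_id not in range(1, 8):
        raise ValueError(f"arch_id must be in 1..7, got {arch_id}")
    region_sizes = tuple(int(s) for s in region_sizes)
    if len(region_sizes) < 2:
        raise ValueError("need at least 2 regions")
    inferred = "single" if arch_id in SINGLE_ARCHS else "dual"
    if mode is None:
        mode = inferred
    if mode != inferred:
        raise ValueError(
            f"architecture {arch_id} is {inferred}-frame; got mode={mode!r}")
    R = len(region_sizes)
    times = 1 if mode == "single" else 2
    h = hidden_per_region
    g = group_width

    input_groups = [(("px", t, r), region_sizes[r])
                    for t in range(times) for r in range(R)]
    l2_groups = [((t, r), h) for t in range(times) for r in range(R)]
    region_mask = _mask_from_groups(
        l2_groups, input_groups,
        lambda o, i: o[0] == i[1] and o[1] == i[2])
    full = lambda o, i: True  # noqa: E731
    out_groups = [(("out",), 1)]

    pairs = list(itertools.combinations(range(R), 2))
    layers = [input_groups, l2_groups]
    masks = [region_mask]
    annotations = ["region" if times == 1 else "region+time"]

    def _add(groups, connected, tag):
        masks.append(_mask_from_groups(groups, layers[-1], connected))
        layers.append(groups)
        annotations.append(tag)

    if arch_id == 1:
        _add(out_groups, full, "s")
    elif arch_id == 2:
        _add(out_groups, full, "s+t")
    elif arch_id == 3:
        _add([(("time", t), g) for t in range(2)],
             lambda o, i: o[1] == i[0], "s")
        _add(out_groups, full, "t")
    elif arch_id == 4:
        _add([(("pair", 0, p), g) for p in pairs],
             lambda o, i: i[1] in o[2], "s(p)")
        _add(out_groups, full, "s")
    elif arch_id == 5:
        _add([(("pair", t, p), g) for t in range(2) for p in pairs],
             lambda o, i: o[1] == i[0] and i[1] in o[2], "s(p)")
        _add(out_groups, full, "s+t")
    elif arch_id == 6:
        _add([(("pair", t, p), g) for t in range(2) for p in pairs],
             lambda o, i: o[1] == i[0] and i[1] in o[2], "s(p)")
        _add([(("time", t), g) for t in range(2)],
             lambda o, i: o[1] == i[1], "s")
        _add(out_groups, full, "t")
    elif arch_id == 7:
        xpairs = [(r1, r2) for r1 in range(R) for r2 in range(R)]
        _add([(("xpair", p), g) for p in xpairs],
             lambda o, i: (i[0] == 0 and i[1] == o[1][0]) or
                          (i[0] == 1 and i[1] == o[1][1]), "s(p)+t")
        _add(out_groups, full, "s")

    return ArchitectureSpec(
        arch_id=arch_id, mode=mode,
        layer_sizes=[sum(w for _, w in lg) for lg in layers],
        masks=masks, annotations=annotations, layer_groups=layers,
        region_sizes=region_sizes, hidden_per_region=h, group_width=g)


# ---------------------------------------------------------------------------
# Lesion grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionJob:
    """One (architecture, dataset-lesion) training job."""

    arch_id: int
    kept_regions: tuple                     # region names retained
    lesion: str                             # "none" | "missing_one" | "single"
    lesioned_region: str | None = None


def enumerate_model_grid(architectures=tuple(range(1, 8)),
                         regions=("motor", "somatosensory", "visual",
                                  "retrosplenial"),
                         lesionable_regions=None,
                         single_region_archs=(1, 2)) -> list[LesionJob]:
    """Enumerate the full lesion-by-architecture job grid.

    Jobs comprise: the full dataset under every architecture; each dataset
    with one region removed, under every architecture; and each dataset
    reduced to a single region, under the architectures meaningful for
    single-region data (1 and 2 — the remaining five all mix multiple
    regions).  With 4 regions and 7 architectures this yields
    7 + 4*7 + 4*2 = 43 jobs.
    """
    architectures = tuple(architectures)
    regions = tuple(regions)
    if lesionable_regions is None:
        lesionable_regions = regions
    lesionable_regions = tuple(lesionable_regions)
    jobs: list[LesionJob] = []
    for a in architectures:
        jobs.append(LesionJob(a, regions, "none"))
    for r in lesionable_regions:
        kept = tuple(x for x in regions if x != r)
        for a in architectures:
            jobs.append(LesionJob(a, kept, "missing_one", r))
    for r in lesionable_regions:
        for a in architectures:
            if a in single_region_archs:
                jobs.append(LesionJob(a, (r,), "single", r))
    return list(dict.fromkeys(jobs))


# ---------------------------------------------------------------------------
# RBM pretraining (contrastive divergence, CD-1)
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class RBMModel:
    """Region-masked restricted Boltzmann machine (logistic units)."""

    weights: np.ndarray                     # (hidden x visible)
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    mask: np.ndarray
    momentum: float = 0.5
    learning_rate: float = 0.1
    epochs_trained: int = 0
    recon_errors: list = field(default_factory=list)

    def hidden_probabilities(self, data: np.ndarray) -> np.ndarray:
        return _sigmoid(data @ self.weights.T + self.hidden_bias)


def train_rbm(data: np.ndarray, mask: np.ndarray, momentum: float = 0.5,
              learning_rate: float = 0.1, epochs: int = 500,
              seed: int = 0, init_scale: float = 0.01) -> RBMModel:
    """Train a masked RBM with one-step contrastive divergence.

    ``data`` must be normalized to [0, 1].  The whole dataset forms one
    batch per epoch (batch size equals the number of time points).  The
    connection mask is applied — masked weights reset to exactly zero — at
    initialization and upon completion of every epoch, so each hidden unit
    only ever carries information from its own cortical region (and time
    point, for dual input).  The mean squared reconstruction error is
    recorded per epoch.
    """
    data = np.asarray(data, dtype=float)
    if data.size and (data.min() < 0 or data.max() > 1):
        raise ValueError("RBM input must be normalized to [0, 1]")
    mask = np.asarray(mask)
    n_hidden, n_visible = mask.shape
    if data.shape[1] != n_visible:
        raise ValueError("data width does not match mask visible size")
    rng = np.random.default_rng(seed)
    W = init_scale * rng.standard_normal((n_hidden, n_visible)) * mask
    vb = np.zeros(n_visible)
    hb = np.zeros(n_hidden)
    vW = np.zeros_like(W)
    vvb = np.zeros_like(vb)
    vhb = np.zeros_like(hb)
    n = max(data.shape[0], 1)
    errors: list[float] = []
    for _ in range(epochs):
        h_prob = _sigmoid(data @ W.T + hb)
        h_state = (rng.random(h_prob.shape) < h_prob).astype(float)
        v_prob = _sigmoid(h_state @ W + vb)
        h_prob2 = _sigmoid(v_prob @ W.T + hb)
        dW = (h_prob.T @ data - h_prob2.T @ v_prob) / n
        dvb = (data - v_prob).mean(axis=0)
        dhb = (h_prob - h_prob2).mean(axis=0)
        vW = momentum * vW + learning_rate * dW
        vvb = momentum * vvb + learning_rate * dvb
        vhb = momentum * vhb + learning_rate * dhb
        W += vW
        vb += vvb
        hb += vhb
        W *= mask
        errors.append(float(np.mean((data - v_prob) ** 2)))
    return RBMModel(weights=W, visible_bias=vb, hidden_bias=hb,
                    mask=mask.astype(np.uint8), momentum=momentum,
                    learning_rate=learning_rate, epochs_trained=epochs,
                    recon_errors=errors)


def sweep_momentum(train_fn, grid, criterion=None):
    """Return the grid momentum minimizing a training criterion.

    ``train_fn(momentum)`` trains one model (typically at reduced epochs)
    and returns either the criterion value directly or an object from which
    ``criterion`` extracts it (e.g. final reconstruction error for RBMs,
    validation MSE for FFNNs).  Ties break toward the smaller momentum;
    grid points whose training diverges are skipped.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("momentum grid is empty")
    best_m, best_v = None, np.inf
    for m in sorted(grid):
        try:
            result = train_fn(m)
        except TrainingDivergedError:
            continue
        value = float(criterion(result)) if criterion is not None else float(result)
        if np.isfinite(value) and value < best_v:
            best_m, best_v = m, value
    if best_m is None:
        raise ValueError("criterion was non-finite for every grid value")
    return best_m


# ---------------------------------------------------------------------------
# FFNN
# ---------------------------------------------------------------------------

@dataclass
class FFNNModel:
    """Masked feed-forward classifier (scaled-tanh hidden, logistic output)."""

    spec: ArchitectureSpec
    weights: list                            # per layer pair, (out x in)
    biases: list
    learning_rate: float = 2.0
    scaling_factor: float = 1.0
    momentum: float = 0.5
    sparsity_target: float = 0.05
    non_sparsity_penalty: float = 0.0
    l2: float = 0.0
    dropout: float = 0.0
    epochs_trained: int = 0
    mse_trace: list = field(default_factory=list)

    # -- forward pass ----------------------------------------------------
    def forward(self, X: np.ndarray) -> list:
        """Activations per layer (input first, logistic output last)."""
        acts = [np.asarray(X, dtype=self.weights[0].dtype)]
        a = acts[0]
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W.T + b
            a = _sigmoid(z) if i == last else TANH_A * np.tanh(TANH_B * z)
            acts.append(a)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1].ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(np.int8)

    def hidden_activations(self, X: np.ndarray, layer: int = 1) -> np.ndarray:
        """Activations of hidden layer ``layer`` (1 = first hidden)."""
        return self.forward(X)[layer]

    # -- loss / gradients -------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Half mean squared error and analytic gradients.

        Returns ``(loss, weight_grads, bias_grads)`` where the loss is
        ``0.5 * mean((y - output)^2)`` plus the optional sparsity penalty
        (inert at the default ``non_sparsity_penalty = 0``).
        """
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        acts = self.forward(X)
        out = acts[-1]
        n = X.shape[0]
        err = y - out
        loss = 0.5 * float(np.mean(err ** 2))
        # output delta: d(loss)/dz for logistic output with squared error
        delta = -err * out * (1.0 - out) / n
        w_grads = [None] * len(self.weights)
        b_grads = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            w_grads[i] = delta.T @ a_prev
            b_grads[i] = delta.sum(axis=0)
            if i > 0:
                back = delta @ self.weights[i]
                a = acts[i]
                fprime = TANH_A * TANH_B * (1.0 - (a / TANH_A) ** 2)
                if self.non_sparsity_penalty > 0:
                    rho_hat = ((a / TANH_A + 1.0) / 2.0).mean(axis=0)
                    sparsity = self.non_sparsity_penalty * \
                        (rho_hat - self.sparsity_target) / (2.0 * TANH_A) / n
                    back = back + sparsity
                delta = back * fprime
        if self.l2 > 0:
            for i, W in enumerate(self.weights):
                w_grads[i] = w_grads[i] + self.l2 * W
                loss += 0.5 * self.l2 * float(np.sum(W ** 2))
        return loss, w_grads, b_grads

    def apply_masks(self) -> None:
        for W, mask in zip(self.weights, self.spec.masks):
            W *= mask

    def max_masked_weight(self) -> float:
        """Largest |weight| over masked entries (0 iff constraints hold)."""
        worst = 0.0
        for W, mask in zip(self.weights, self.spec.masks):
            blocked = np.abs(W[mask == 0])
            if blocked.size:
                worst = max(worst, float(blocked.max()))
        return worst


def init_ffnn_from_rbm(rbm: RBMModel, spec: ArchitectureSpec, seed: int = 0,
                       dtype=np.float64, init_gain: float = 1.0,
                       **hyper) -> FFNNModel:
    """Initialize a masked FFNN, copying layer-1 weights from the RBM.

    Layer-1 weights and hidden biases are bit-copies of the trained RBM;
    deeper layers draw uniformly from ±gain·sqrt(6 / (fan_in + fan_out))
    (Glorot range, gain 1 by default — larger gains push the logistic
    output unit into saturation at initialization, from which full-batch
    squared-error descent cannot recover) and are masked immediately.
    """
    if rbm.weights.shape != tuple(spec.masks[0].shape):
        raise ValueError(
            f"RBM shape {rbm.weights.shape} does not match architecture "
            f"layer-1 mask {spec.masks[0].shape}")
    rng = np.random.default_rng(seed)
    weights = [rbm.weights.astype(dtype).copy()]
    biases = [rbm.hidden_bias.astype(dtype).copy()]
    for mask in spec.masks[1:]:
        fan_out, fan_in = mask.shape
        scale = init_gain * np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-scale, scale, size=mask.shape).astype(dtype)
        weights.append(W * mask)
        biases.append(np.zeros(fan_out, dtype=dtype))
    model = FFNNModel(spec=spec, weights=weights, biases=biases, **hyper)
    model.apply_masks()
    return model


def train_ffnn(model: FFNNModel, X_train: np.ndarray, y_train: np.ndarray,
               epochs: int = 2000, X_val: np.ndarray | None = None,
               y_val: np.ndarray | None = None) -> dict:
    """Full-batch momentum gradient descent on the squared-error loss.

    The batch is the whole training set.  Masks are reapplied (masked
    weights zeroed) after every epoch.  The learning rate is multiplied by
    ``model.scaling_factor`` each epoch (1 = constant).  Records the plain
    train MSE per epoch in ``model.mse_trace`` and returns a metrics dict
    with final train/val MSE.

    Raises
    ------
    TrainingDivergedError
        If the loss becomes non-finite; the exception carries the epoch.
    """
    if X_train.shape[1] != model.spec.layer_sizes[0]:
        raise ValueError(
            f"feature count {X_train.shape[1]} does not match input layer "
            f"size {model.spec.layer_sizes[0]}")
    lr = model.learning_rate
    vel_w = [np.zeros_like(W) for W in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    y = np.asarray(y_train, dtype=float)
    for epoch in range(epochs):
        loss, w_grads, b_grads = model.loss_and_grads(X_train, y)
        if not np.isfinite(loss):
            raise TrainingDivergedError(epoch)
        for i in range(len(model.weights)):
            vel_w[i] = model.momentum * vel_w[i] - lr * w_grads[i]
            vel_b[i] = model.momentum * vel_b[i] - lr * b_grads[i]
            model.weights[i] += vel_w[i]
            model.biases[i] += vel_b[i]
        model.apply_masks()
        if not all(np.all(np.isfinite(W)) for W in model.weights):
            raise TrainingDivergedError(epoch)
        model.mse_trace.append(2.0 * loss)   # plain MSE
        lr *= model.scaling_factor
    model.epochs_trained += epochs
    metrics = {"train_mse": _mse(model, X_train, y_train),
               "train_accuracy": _accuracy(model, X_train, y_train)}
    if X_val is not None and len(X_val):
        metrics["val_mse"] = _mse(model, X_val, y_val)
        metrics["val_accuracy"] = _accuracy(model, X_val, y_val)
    return metrics


def _mse(model: FFNNModel, X, y) -> float:
    return float(np.mean((np.asarray(y, float) - model.predict_proba(X)) ** 2))


def _accuracy(model: FFNNModel, X, y) -> float:
    return float(np.mean(model.predict(X) == np.asarray(y)))


def evaluate(model: FFNNModel, X, y) -> dict:
    """Test-set MSE, accuracy and hard predictions (output >= 0.5)."""
    proba = model.predict_proba(X)
    pred = (proba >= 0.5).astype(np.int8)
    y = np.asarray(y)
    return {"mse": float(np.mean((y.astype(float) - proba) ** 2)),
            "accuracy": float(np.mean(pred == y)),
            "predictions": pred, "probabilities": proba}
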