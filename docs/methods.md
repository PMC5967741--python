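# Methods

This note documents the models and procedures implemented in
`avalanchekit`, the assumptions behind them, the parameters that matter,
and the choices made where the design was genuinely open.

## Signal model and synthetic data

The analysis assumes optical voltage data: per-pixel time series sampled at
50 Hz (20 ms frame interval) in which a positive excursion reflects a
synchronized transition of the local pyramidal-cell population to the
up-state. The synthetic generator (`avalanchekit.synthetic`) emulates the
two statistical regimes the detection chain relies on:

* **Quiescence** — stationary Gaussian AR(1) noise per pixel,
  `x_t = a·x_{t−1} + σ√(1−a²)·ε_t`, with coefficient `a = 0.5` and s.d.
  `σ = 1` by default. Band-passed optical data are temporally correlated;
  AR(1) is the simplest process with that property. No quantitative
  description of real quiescent-period statistics is asserted — the AR(1)
  default is a stand-in, and the autocorrelation coefficient is exposed in
  `SimulationConfig`.
* **Avalanches** — a disc-shaped wavefront of at least `cluster_px` pixels
  (default 12; the realized disc carries one radius step of headroom)
  elevated by `amplitude_sd` (default 5) times the noise s.d., whose
  center travels in a straight line from the origin region toward the
  target region over `duration_frames` frames (default 6). Only the moving
  front is elevated, so each frame produces a fresh set of
  below-to-above threshold crossings — the signal shape a point-process
  detector responds to. The per-frame step size is computed from the disc
  geometry so the newly covered pixel count stays above the configured
  cluster size; routes whose geometry cannot deliver that raise a
  placement error rather than silently emitting undetectable events.

The cortical geometry is four jittered rectangular quadrants (motor,
somatosensory, visual, retrosplenial) tiling the grid. This deliberately
does not mimic any real hemisphere's hand-drawn regions; it preserves the
properties downstream stages need (disjoint, connected, ≥ 200 pixels, so
2-pixel erosion and 10×10 entropy windows stay valid). Default routing
sends half the cascades visual → motor with motor and retrosplenial loops
and somatosensory → motor traffic making up the rest, mirroring the
trajectory classes most prominent in this kind of data. `awake_config()`
(frequent, small, amplitude-jittered, possibly concurrent events) and
`anesthetized_config()` (sparse, large, stereotyped events) are presets for
probing regime differences; no test asserts architecture rankings on them.

What passing tests on this generator do **not** show: robustness to
hemodynamic artifacts, shot noise, gain inhomogeneity, spatially correlated
noise, drifting baselines, or realistic region shapes. The generator
starts at the voltage signal; everything optical is out of scope.

## Preprocessing

Band-pass filtering uses a zero-phase (forward–backward) Butterworth
design, 0.1–20 Hz by default. Zero-phase filtering avoids group lag that
would shift avalanche onsets relative to the unfiltered signal. The
default order is 3: under forward–backward application a 2nd-order design
attenuates a mid-band 10 Hz tone by ~5.5%, while order 3 keeps it under 3%
and suppresses a 24 Hz tone by ~94% — the response the pipeline documents.
The order is a parameter.

Z-scoring uses the sample s.d. (ddof = 1); at the thousands of frames this
pipeline targets the distinction from the population s.d. is negligible.
Pixels whose series is constant (s.d. below numerical noise) cannot be
standardized and are dropped from the validity mask with a warning.
Z-scoring is applied per simulated segment; for multi-segment recordings
the choice of per-segment vs concatenated standardization is the caller's
(segments are separate `ImageSequence` objects). An optional
`discard_initial` drops the first 10 s of a recording (shutter/onset
artifacts); it is off by default for synthetic data, which has no such
artifacts.

## Avalanche detection

* **Point process**: pixel flagged at `t` iff `value(t) ≥ 3` s.d. and
  `value(t−1) < 3` s.d.; frame 0 is never flagged. Above-threshold samples
  after a crossing are not re-flagged until the signal dips below
  threshold — this avoids double-counting pixels and tracks the activity
  wavefront rather than the already-active area.
* **Cluster criterion**: a frame qualifies if some connected component of
  its flags reaches `min_cluster_px` (default 10). The criterion is
  implemented as ≥, which makes five 10-pixel frames the smallest legal
  avalanche (50 pixels, 100 ms) — consistent with the stated minima; a
  `strict` switch gives the > variant. Connectivity is 8-connected by
  default (4-connected available).
* **Context rule**: avalanche label requires the frame and its 2 preceding
  and 2 following frames to qualify; quiescence requires all five to be
  clean; everything else — including the un-judgeable first/last two
  frames — is excluded. Frames with only sub-criterion clusters (1–9
  flagged pixels) still count as clean for quiescence purposes: the
  criterion defines what a cluster is.
* **Events**: maximal runs of *qualifying* frames containing at least one
  avalanche-labeled frame. Using qualifying frames (not avalanche-labeled
  frames) as boundaries prevents the context rule from eroding two frames
  off each end of every event. Event size sums all qualifying clusters in
  each frame of the run; the duration uses the nominal 20 ms frame
  interval. Both labeling and extraction are verified exactly against an
  independent brute-force BFS reference on random stacks.

## Balanced datasets

The minority class (usually avalanche) governs all counts: each class
contributes `floor(0.8·m)` / `floor(0.1·m)` / remainder frames to
train/val/test, drawn without replacement, seeded. Splits are frame-level
by default, matching the convention of splitting images; because
temporally adjacent frames are near-duplicates, frame-level splits
overstate generalization — a consideration documented here rather than
silently changed. Feature vectors are region-block-ordered pixel values of
the 2-pixel-eroded regions; dual-frame examples append the preceding
frame's block (the example's label is that of T1). Min-max normalization
statistics come from the training partition only, to avoid leakage;
val/test values are clipped to [0, 1].

## Constrained networks

Seven architectures are defined entirely by binary connection masks; see
`nets.build_architecture` for the exact block structure per architecture
(region-grouped first hidden layer; region pairs `s(p)`; per-time groups;
ordered cross-time pairs `s(p)+t`; single logistic output). Group width
above layer 2 defaults to 1 unit, reproducing the illustrative three-region
models (third layers of 3, 6 and 9 units for architectures 4, 5 and 7); it
is configurable (e.g. 10 to mirror the layer-2 per-region width). For the
lesion grid, single-region datasets support only architectures 1 and 2 —
the other five all mix multiple regions — giving 7 + 4·7 + 4·2 = 43 jobs
on four regions.

**RBM pretraining**: CD-1 with logistic units, full-batch (batch size equal
to the number of time points), learning rate α = 0.1, momentum from a grid
sweep (0 to 1 in steps of 0.1) selected by final reconstruction error.
The region mask is applied at initialization and at the end of every
epoch, so each hidden unit only ever carries information from one cortical
region (and one time point in dual mode). Desk-scale epoch defaults are
5×10² for sweeps and 5×10³ for the final model; both are configurable
upward.

**FFNN training**: full-batch gradient descent with momentum on the squared
error; hidden activation `f(x) = 1.7159·tanh(2x/3)` (the "optimal"
scaled hyperbolic tangent), logistic output thresholded at 0.5. Learning
rate 2 with per-epoch scaling factor 1 (constant). Sparsity target (0.05),
non-sparsity penalty (0), L2 (0) and dropout (0) are carried as fields;
with a zero penalty the sparsity machinery is inert, which is the default
reading implemented here. Layer-1 weights and biases are copied from the
pretrained RBM; deeper layers draw from the Glorot uniform range
±√(6/(fan_in+fan_out)). The 4×-wider variant of that range (the rule used
by older sigmoid-network toolboxes) saturates the single logistic output at
initialization — |pre-activation| ≈ 16 — and full-batch squared-error
descent cannot escape the resulting flat region; `init_gain` exposes the
multiplier for anyone wanting the older behavior. Masks are re-applied
after every epoch, so `max |masked weight| = 0` exactly in every trained
model; analytic gradients are verified against central finite differences
to 1e-5 relative error.

At learning rate 2 the momentum value decides between convergence,
oscillation and collapse to the always-0.5 output — which is precisely why
momentum is swept per model on validation MSE rather than fixed. The
pipeline's `momentum_sweep` option performs the RBM sweep (reconstruction
error) and the FFNN sweep (validation MSE at reduced epochs, default 200)
per job; with the sweep disabled the default momentum is 0, the most
robust single value. Sweeps retrain from a fresh seed per grid point; ties
break toward the smaller momentum.

## Pattern maps

Hidden activations of the **first hidden layer** (the RBM-initialized,
region-grouped layer — the only layer shared by all seven architectures,
which keeps cross-architecture comparisons meaningful) are clustered with
k-means++ (squared Euclidean), k = 4, best of 10 restarts by within-cluster
sum of squared distances. k = 4 consistently separates two avalanche and
two quiescence types; a different k or hidden layer can be passed
explicitly. Each cluster's identity is the majority true label of its
members; "correctly clustered" frames are those matching their cluster's
identity.

Back-projection is linear: the centroid is multiplied through the
transposes of the masked weight matrices down to the input layer, then
scattered into pixel space via the region-block layout. Activation
nonlinearities are ignored — the result is read as an intensity map, and
linearity gives the exact support guarantee that a region-constrained
hidden unit back-projects to zero outside its region (mask algebra, no
tolerance). Centroids are back-projected directly (no averaging over
members' individual back-projections). Dual-frame models yield T1 and T2
maps plus their mean; intensity maps are min-max normalized per cortical
region, activity maps (sums of correctly clustered z-scored frames) per
map.

## Spatial entropy and trajectories

Spatial entropy of a normalized map is computed per 10×10 window:
`H = −∑ p log₂ p` over a histogram of the window's intensities with 10
equal-width bins on [0, 1] (the bin count is a parameter and is reported
with results). Windows are anchored at every pixel but only windows fully
inside the valid area are scored, avoiding edge-padding artifacts. The
window entropies form the sample for pooled-variance two-sample t-tests
(df = n₁ + n₂ − 2) — per map, with pooling across maps available, which is
the reading consistent with the large degrees of freedom such comparisons
report.

Trajectories come directly from the point-process clusters: the origin
(destination) is the region containing the centroid of the **largest**
qualifying cluster in the event's first (last) frame; a centroid on
background is assigned the nearest region with a warning. Origin equal to
destination is a loop. Counts aggregate to rates that sum to 1 within each
(cluster type, state) group.

## Pipeline conventions

Frames and pixel coordinates are 0-based; all intervals are half-open
`[start, end)`. Every stage archives the resolved configuration beside its
outputs and logs its parameters, counts and timings; all randomness derives
from one seed through fixed-order per-stage children, so identical
configurations reproduce identical artifacts (bit-exact for integer
outputs). Sequences, point-process stacks and maps are multi-frame float32
TIFF; masks integer TIFF; events, splits, metrics, entropies and
trajectories CSV; ground truth, configurations and summaries JSON; example
matrices NPZ (documented layout: `X_/y_` per partition plus the region
order and sizes).

## Problem sizes and defaults used in the tests

The test suite exercises the full chain at desk scale: 48×48 grids with
~45 cascades for training runs (RBM 300 epochs, FFNN momentum sweep at
1000 epochs, final training at 2000 epochs), 120×120 grids for detection
and trajectory recovery, 200 random 50×30×30 stacks for the brute-force
equivalence check, and 5 000-frame runs for noise calibration checks.
These sizes were chosen as the smallest at which every stage's behavior is
unambiguous; all of them are parameters, and nothing in the implementation
is specific to them.

## Known limitations

* The generator's cascades are geometric (linear paths, disc fronts);
  real avalanches branch, merge and stall. Detection of such morphologies
  is untested here.
* Spatial-adjacency constraints between temporally consecutive clusters
  are not part of the avalanche definition (temporal contiguity only), and
  avalanche size/duration power-law statistics are out of scope.
* Full-batch training with learning rate 2 is usable at desk scale but
  momentum selection is essential (see above); very large inputs would
  need a smaller rate or mini-batching, neither of which is implemented.
* No multiple-testing correction is applied across entropy t-tests; raw
  p-values are reported.
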