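import numpy as np
import pytest

import avalanchekit as ak


@pytest.fixture(scope="session")
def region_mask():
    """A 120x120 four-region cortex used across detection tests."""
    return ak.generate_region_masks((120, 120), seed=1)


@pytest.fixture(scope="session")
def default_simulation(region_mask):
    """Default-regime simulation with its ground truth (10 planted events)."""
    config = ak.SimulationConfig(n_frames=700, event_rate=1000 * 10 / 700,
                                 duration_frames=6, seed=3)
    seq, truth = ak.simulate_sequence(config, region_mask)
    return config, seq, truth


@pytest.fixture(scope="session")
def detected(default_simulation):
    """z-score -> point process -> labels -> events for the default run."""
    _, seq, _ = default_simulation
    zseq = ak.zscore_pixels(seq)
    pp = ak.binarize_transitions(zseq)
    labeling = ak.label_frames(pp)
    events = ak.extract_avalanches(pp, labeling)
    return zseq, pp, labeling, events


def make_cluster_stack(n_frames, shape, frames_with_clusters, cluster_px=12,
                       corner=(2, 2)):
    """Binary stack with one square-ish connected cluster on chosen frames."""
    flags = np.zeros((n_frames, *shape), dtype=np.uint8)
    side = int(np.ceil(np.sqrt(cluster_px)))
    r0, c0 = corner
    placed = 0
    coords = []
    for r in range(side):
        for c in range(side):
            if placed < cluster_px:
                coords.append((r0 + r, c0 + c))
                placed += 1
    for t in frames_with_clusters:
        for r, c in coords:
            flags[t, r, c] = 1
    return flags
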