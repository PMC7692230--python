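import numpy as np
import pytest

from retimetrics import octa
from retimetrics.synth import generate_bscan, generate_vessel_network


@pytest.fixture(scope="session")
def network_256():
    """One noise-free generated network with its ground truth."""
    angiogram, truth = generate_vessel_network(
        size_px=256, seed=7, target_density=0.35, noise_level=0)
    return angiogram, truth


@pytest.fixture(scope="session")
def skeleton_256(network_256):
    angiogram, _ = network_256
    return octa.skeletonize(octa.binarize(angiogram))


@pytest.fixture(scope="session")
def clean_bscan():
    """Speckle-free B-scan with no foci."""
    record, _ = generate_bscan(speckle_level=0, seed=0)
    return record


def brute_force_box_counts(mask: np.ndarray, sizes) -> list[int]:
    """Independent nested-loop box counter (oracle for the FD ladder)."""
    h, w = mask.shape
    counts = []
    for s in sizes:
        n = 0
        for r0 in range(0, h, s):
            for c0 in range(0, w, s):
                if mask[r0:r0 + s, c0:c0 + s].any():
                    n += 1
        counts.append(n)
    return counts
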