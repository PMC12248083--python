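import numpy as np
import pytest
from hypothesis import settings

import virtualhic as vh
from virtualhic.synthetic import CompartmentTrack, generate_native_ensemble

settings.register_profile("suite", derandomize=True, max_examples=10,
                          deadline=None)
settings.load_profile("suite")


def make_chain(n_beads: int, seed: int = 0, bond_range=(1.2, 1.45),
               min_sep: float = 0.95) -> np.ndarray:
    """Random FENE-safe, overlap-free chain for force/energy tests."""
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    for i in range(1, n_beads):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= rng.uniform(*bond_range) / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.linalg.norm(pos[:i] - cand, axis=1).min() > min_sep:
                pos[i] = cand
                break
        else:  # pragma: no cover - practically unreachable at these sizes
            pos[i] = cand
    return pos


@pytest.fixture(scope="session")
def chain20():
    return make_chain(20, seed=3)


@pytest.fixture(scope="session")
def ensemble240():
    """Small compartmentalised ensemble shared by analysis-level tests."""
    track = CompartmentTrack.blocks(240, 4)
    confs, track, _ = generate_native_ensemble(40, 240, track, seed=2024,
                                               anneal_steps=8000)
    return confs, track


@pytest.fixture(scope="session")
def natives1000():
    """Scaled-down study ensemble: 10 structures x 1000 beads."""
    track = CompartmentTrack.blocks(1000, 5)
    confs, track, _ = generate_native_ensemble(10, 1000, track, seed=77,
                                               anneal_steps=10000)
    return confs, track
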