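import numpy as np
import pytest

from axonlength import SynthParams, extract_segments, synth_axon


@pytest.fixture()
def tiny_swc(tmp_path):
    """Two-point file: a soma and one axonal child 10 µm above it."""
    p = tmp_path / "tiny.swc"
    p.write_text("# soma + axon edge\n1 1 0 0 0 1 -1\n2 2 0 0 10 0.5 1\n")
    return p


@pytest.fixture(scope="session")
def class4_morph():
    """Small local arbor reused across tests (exact 10 000 µm budget)."""
    return synth_axon(SynthParams(class_label=4, target_length=10_000.0, seed=11))


@pytest.fixture(scope="session")
def class4_segments(class4_morph):
    return extract_segments(class4_morph)


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
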