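import numpy as np
import pytest

from gptransfer import AlignedDesign, SimConfig, simulate_dataset


def random_design(n, p, seed, y=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if y is None:
        y = rng.normal(size=n)
    return AlignedDesign(X, y, tuple(f"L{i}" for i in range(n)))


@pytest.fixture(scope="session")
def small_dataset():
    """Two-environment simulated dataset small enough for repeated evaluation."""
    cfg = SimConfig(n_lines_total=120, p_markers=60, shared_line_fraction=0.5,
                    effect_correlation=0.9, h2_proxy=0.6, h2_goal=0.6, seed=42)
    return simulate_dataset(cfg)
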