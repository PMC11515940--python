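import numpy as np
import pytest
from hypothesis import settings

from rips import RnaTemplate, SimParams, standin_oligo

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def oligo19() -> RnaTemplate:
    """19-nt stand-in with Ψ at position 4 (protection-product geometry)."""
    return standin_oligo("o19", 19, 4, seed=1)


@pytest.fixture
def oligo60() -> RnaTemplate:
    """60-nt stand-in with Ψ at position 30 (sequencing-validation geometry)."""
    return standin_oligo("o60", 60, 30, seed=2)


@pytest.fixture
def oligo32() -> RnaTemplate:
    """32-nt stand-in with Ψ at position 16 (mixture-scenario ssRNA)."""
    return standin_oligo("o32", 32, 16, seed=3)


@pytest.fixture
def deterministic_params() -> SimParams:
    """All chemistry deterministic: every Ψ labeled, digested, RT-stopped."""
    return SimParams(
        p_label_ss=1.0, p_engage=1.0, p_protect=1.0, p_rt_stop=1.0,
        p_bg_stop=0.0, seq_error=0.0, n_molecules=100, min_fragment_len=1, seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
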