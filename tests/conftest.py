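from __future__ import annotations

import numpy as np
import pytest

from famforge import synthetic_data as sd

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def small_family():
    """A compact planted family reused by search/domain tests."""
    spec = sd.SynthFamilySpec(
        n_background_proteins=120,
        n_family_members=20,
        domain_identity_to_seed=0.8,
        cterm_domain_mix={"Kelch": 0.3, "LRR": 0.2, "unknown": 0.5},
        seed=42,
    )
    return sd.make_family_proteome(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
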