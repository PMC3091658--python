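from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from estdd.model import LibraryModel
from estdd.simulate import simulate_pair, simulate_transcriptome

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_pair():
    """Two small noisy libraries over 30 transcripts, with truth."""
    txs = simulate_transcriptome(30, (900, 120), seed=11)
    ab = {t.id: 1 / 30 for t in txs}
    model_a = LibraryModel("JD", 300, ab, error_rate=0.01, seed=101)
    model_b = LibraryModel("JG", 250, ab, error_rate=0.01, seed=102)
    return simulate_pair(txs, model_a, model_b)
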