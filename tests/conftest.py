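"""Shared fixtures: hand-built chains and small synthetic proteomes."""

from __future__ import annotations

import numpy as np
import pytest

from lcdstruct.core import AMINO_ACIDS, AnnotatedChain
from lcdstruct.simulate import demo_spec, generate_proteome


@pytest.fixture
def make_chain():
    """Factory for chains from (sequence, ss, disorder-string) triples."""

    def _make(
        sequence: str,
        ss: str | None = None,
        disorder: str | None = None,
        chain_id: str = "TEST_A",
    ) -> AnnotatedChain:
        n = len(sequence)
        ss = ss if ss is not None else "-" * n
        mask = (
            np.array([ch == "X" for ch in disorder])
            if disorder is not None
            else np.zeros(n, dtype=bool)
        )
        return AnnotatedChain(chain_id, sequence, ss, mask)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def random_12mers(rng):
    """10,000 random canonical 12-mers for entropy oracle checks."""
    letters = np.array(list(AMINO_ACIDS))
    draws = rng.integers(0, 20, size=(10_000, 12))
    return ["".join(letters[row]) for row in draws]


@pytest.fixture(scope="session")
def small_proteome():
    """A 20-chain synthetic proteome with blocks and dose responses."""
    return generate_proteome(demo_spec(n_chains=20, seed=101))


@pytest.fixture(scope="session")
def medium_proteome():
    """A 120-chain synthetic proteome for statistics-level checks."""
    return generate_proteome(demo_spec(n_chains=120, seed=202))
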