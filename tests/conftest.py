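"""Shared fixtures: small synthetic databases and canned readouts."""

from __future__ import annotations

import numpy as np
import pytest

from protident import (
    DeviceConfig,
    ProteinRecord,
    SequenceDatabase,
    SynthDbSpec,
    generate_database,
)


@pytest.fixture(scope="session")
def tiny_db() -> SequenceDatabase:
    """Five distinct same-length random sequences (uniform residue use)."""
    return generate_database(
        SynthDbSpec(n=5, length_distribution=("fixed", 30), background="uniform", seed=101)
    )


@pytest.fixture(scope="session")
def small_db() -> SequenceDatabase:
    """Thirty human-like sequences of moderate length for pipeline tests."""
    return generate_database(
        SynthDbSpec(
            n=30,
            length_distribution=("uniform", 40, 80),
            background="human-like",
            seed=202,
        )
    )


@pytest.fixture(scope="session")
def balanced_db() -> SequenceDatabase:
    """Equal-length records with an exactly uniform overall composition.

    Each sequence is a permutation of the 20 amino acids, so the database
    background is exactly 1/20 per residue — the setting in which profile
    scores depend only on target length.
    """
    rng = np.random.default_rng(7)
    from protident import AMINO_ACIDS

    records = []
    for i in range(6):
        letters = list(AMINO_ACIDS)
        rng.shuffle(letters)
        records.append(ProteinRecord(f"PERM{i:02d}", "".join(letters)))
    return SequenceDatabase.from_records(records)


@pytest.fixture
def device_half() -> DeviceConfig:
    return DeviceConfig(p_max=0.5)
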