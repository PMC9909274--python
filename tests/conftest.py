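"""Shared fixtures: the hand-worked example chain and small random inputs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tetraface import ChainRecord, GeometricProfile
from tetraface._aadata import ALPHABET

#: sequence and ASA values of the hand-worked featurization example.
WORKED_SEQUENCE = "ACAGAHHAALKAYAW"
WORKED_ASA = [6, 4, 7, 5, 7, 8, 2, 8, 9, 3, 7, 11, 10, 14, 15]


def make_chain(
    sequence: str,
    coords: np.ndarray | None = None,
    chain_id: str = "A",
) -> ChainRecord:
    """Build a ChainRecord, tolerating out-of-range test lengths."""
    if coords is None:
        coords = np.column_stack(
            [np.arange(len(sequence)) * 3.8, np.zeros(len(sequence)), np.zeros(len(sequence))]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ChainRecord(chain_id=chain_id, sequence=sequence, ca_coords=coords)


def random_chain(
    rng: np.random.Generator, L: int, chain_id: str = "A"
) -> tuple[ChainRecord, GeometricProfile]:
    """A random chain with random coordinates and a random profile."""
    seq = "".join(rng.choice(list(ALPHABET), size=L))
    coords = rng.normal(scale=10.0, size=(L, 3))
    chain = make_chain(seq, coords, chain_id)
    vals = np.abs(rng.normal(5.0, 3.0, size=(L, 5)))
    return chain, GeometricProfile(vals)


@pytest.fixture
def worked_chain() -> tuple[ChainRecord, GeometricProfile]:
    chain = make_chain(WORKED_SEQUENCE)
    vals = np.zeros((len(WORKED_SEQUENCE), 5))
    vals[:, 0] = WORKED_ASA
    return chain, GeometricProfile(vals)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
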