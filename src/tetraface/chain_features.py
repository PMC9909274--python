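"""Chain-pair featurization: change sequences and the 20 x 24 feature map.

For each amino-acid type x in a chain, the positions of its occurrences and
the corresponding geometric property values define a *position change
sequence* (successive position differences) and five *geometry change
sequences* (successive property-value differences).  Four summary statistics
of the position sequence (frequency, mean, min, max) and four per property
(mean, min, max, mean ratio) give 4 + 4x5 = 24 features per letter, hence a
20 x 24 matrix Q per chain.  A chain pair is represented by the elementwise
absolute difference S = |Q_a - Q_b|, standardized over all 480 entries.

Degenerate conventions: a letter occurring once yields a single-element
change sequence equal to the deviation of its position (value) from the
chain-wide mean position (value); an absent letter yields [0] and an
all-zero feature row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._aadata import ALPHABET
from .structures import ChainRecord, GeometricProfile, TetramerComplex

#: column order of the 24 per-letter features.
COLUMN_ORDER = ["F", "A", "B", "M"] + [
    f"{s}{i}" for i in range(1, 6) for s in ("A", "B", "M", "R")
]


@dataclass
class ChangeSequences:
    """Position and geometry change sequences for one amino-acid letter."""

    letter: str
    positions: np.ndarray  # 1-based occurrence positions, ascending
    f: np.ndarray  # position change sequence
    f_geom: np.ndarray  # (5, len(f)) geometry change sequences

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class FeatureMap:
    """Standardized 20 x 24 chain-pair matrix plus sample metadata."""

    matrix: np.ndarray
    complex_id: str = ""
    chain_pair: tuple[str, str] = ("", "")
    label: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (20, 24):
            raise ValueError(f"feature map must be 20x24, got {self.matrix.shape}")


def number_sequences(chain: ChainRecord, profile: GeometricProfile) -> np.ndarray:
    """Map the chain to its five geometric number sequences, shape (5, L)."""
    if len(profile) != len(chain):
        raise ValueError(
            f"profile has {len(profile)} rows but chain {chain.chain_id} "
            f"has {len(chain)} residues"
        )
    return profile.values.T.copy()


def change_sequences(
    chain: ChainRecord, profile: GeometricProfile, x: str
) -> ChangeSequences:
    """Position and geometry change sequences of letter ``x`` in the chain."""
    if x not in ALPHABET:
        raise ValueError(f"letter {x!r} not in the amino-acid alphabet")
    seqs = number_sequences(chain, profile)
    L = len(chain)
    positions = np.array(
        [j + 1 for j, aa in enumerate(chain.sequence) if aa == x], dtype=int
    )
    n = len(positions)
    if n > 1:
        f = np.diff(positions).astype(float)
        f_geom = np.diff(seqs[:, positions - 1], axis=1)
    elif n == 1:
        f = np.array([positions[0] - (L + 1) / 2.0])
        f_geom = (seqs[:, positions[0] - 1] - seqs.mean(axis=1))[:, None]
    else:
        f = np.array([0.0])
        f_geom = np.zeros((5, 1))
    return ChangeSequences(letter=x, positions=positions, f=f, f_geom=f_geom)


def position_stats(cs: ChangeSequences, L: int) -> tuple[float, float, float, float]:
    """Frequency, mean, min and max of the position change sequence.

    The frequency is the occurrence count over the chain length; the mean
    divides the change-sequence sum by the occurrence count n (not by the
    sequence length n-1).
    """
    n = cs.n
    F = n / L
    if n == 0:
        return F, 0.0, 0.0, 0.0
    A = float(cs.f.sum() / n) if n > 1 else float(cs.f[0])
    return F, A, float(cs.f.min()), float(cs.f.max())


def geometry_stats(
    cs: ChangeSequences, i: int, A_x: float
) -> tuple[float, float, float, float]:
    """Mean, min, max of geometry change sequence ``i`` (0-based) and the
    ratio of that mean to the position-sequence mean ``A_x`` (0 when A_x=0)."""
    n = cs.n
    if n == 0:
        return 0.0, 0.0, 0.0, 0.0
    g = cs.f_geom[i]
    A_i = float(g.sum() / n) if n > 1 else float(g[0])
    R = A_i / A_x if A_x != 0 else 0.0
    return A_i, float(g.min()), float(g.max()), R


def chain_matrix(chain: ChainRecord, profile: GeometricProfile) -> np.ndarray:
    """The 20 x 24 per-chain matrix Q, rows in fixed alphabet order."""
    L = len(chain)
    Q = np.zeros((20, 24))
    for u, x in enumerate(ALPHABET):
        cs = change_sequences(chain, profile, x)
        F, A, B, M = position_stats(cs, L)
        row = [F, A, B, M]
        for i in range(5):
            row.extend(geometry_stats(cs, i, A))
        Q[u] = row
    return Q


def standardize(S: np.ndarray) -> np.ndarray:
    """Zero-mean unit-population-σ standardization over all entries.

    A constant matrix (σ = 0) standardizes to all zeros.
    """
    sigma = S.std()
    scale = np.abs(S).max()
    if sigma <= 1e-12 * max(scale, 1.0):
        return np.zeros_like(S)
    return (S - S.mean()) / sigma


def pair_feature_map(
    Q_a: np.ndarray,
    Q_b: np.ndarray,
    *,
    complex_id: str = "",
    chain_pair: tuple[str, str] = ("", ""),
    label: int | None = None,
    standardized: bool = True,
) -> FeatureMap:
    """Chain-pair sample S = |Q_a - Q_b|, standardized per sample."""
    Q_a, Q_b = np.asarray(Q_a, float), np.asarray(Q_b, float)
    if Q_a.shape != (20, 24) or Q_b.shape != (20, 24):
        raise ValueError("chain matrices must be 20x24")
    S = np.abs(Q_a - Q_b)
    if standardized:
        S = standardize(S)
    return FeatureMap(S, complex_id=complex_id, chain_pair=chain_pair, label=label)


def complex_feature_maps(
    complex_: TetramerComplex,
    profiles: dict[str, GeometricProfile],
    labels: dict[tuple[str, str], bool] | None = None,
) -> list[FeatureMap]:
    """The six chain-pair feature maps of a tetramer, in fixed pair order."""
    Q = {
        cid: chain_matrix(complex_.chain(cid), profiles[cid])
        for cid in complex_.chain_ids
    }
    maps = []
    for cid1, cid2 in complex_.chain_pairs():
        lab = None
        if labels is not None:
            lab = int(labels[(cid1, cid2)])
        maps.append(
            pair_feature_map(
                Q[cid1],
                Q[cid2],
                complex_id=complex_.complex_id,
                chain_pair=(cid1, cid2),
                label=lab,
            )
        )
    return maps
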