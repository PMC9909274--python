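"""Residue-pair featurization: 460 features per residue, 920 per pair.

Sequence block (155): for each of the five physicochemical properties,
forward/backward k-interval product factors (k = 1..10, circular sequence
indexing with head-to-tail wrap) and k-average cumulation factors
(k = 1..10, circular window mean), plus the central residue's five raw
physicochemical values.

Structure block (305): residues are ranked by ascending Euclidean Cα
distance from the central residue (ties broken by ascending sequence
position).  For each of the five geometric properties, residue k-interval
product factors and k-average cumulation factors over the 20 nearest
residues (k = 1..20), and distance-weighted neighbour values
ρ_ξ = ω_ξ · φ(λ_ξ) with ω_ξ = exp(−d_ξ²(k+1)/Σ_{ξ=1}^{k+1} d_ξ²) at k = 20,
plus the central residue's five raw geometric values.  Structure features
need 21 spatial neighbours, so chains must have at least 22 residues.

A residue pair is the order-sensitive concatenation (chain-1 residue first)
of two 460-vectors.  All positions in this module are 0-based indices into
the retained-residue sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._aadata import PHYSCHEM_PROPERTIES
from .structures import ChainRecord, GeometricProfile, PhyschemTable

N_SEQ_FEATURES = 155
N_STRUCT_FEATURES = 305
N_RESIDUE_FEATURES = 460
N_PAIR_FEATURES = 920

K_SEQ = 10  # sequence-offset range
K_STRUCT = 20  # spatial-neighbour range


@dataclass
class NeighborOrder:
    """Other residues ranked by ascending Cα distance from residue j."""

    center: int
    lambda_: np.ndarray  # 0-based positions, length L-1
    d: np.ndarray  # matching distances, non-decreasing


@dataclass
class ResiduePairVector:
    vector: np.ndarray
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, float)
        if self.vector.shape != (N_PAIR_FEATURES,):
            raise ValueError(
                f"pair vector must have {N_PAIR_FEATURES} entries, "
                f"got {self.vector.shape}"
            )


def physchem_sequences(chain: ChainRecord, table: PhyschemTable) -> np.ndarray:
    """Map the chain to its five physicochemical number sequences, (5, L)."""
    rows = []
    for aa in chain.sequence:
        rows.append(table.row(aa))
    return np.asarray(rows, float).T


def aaipf(seq: np.ndarray, j: int, k: int) -> tuple[float, float]:
    """Forward/backward k-interval product factors at residue j (0-based).

    forward = Φ_j·Φ_{j-k}/k and backward = Φ_j·Φ_{j+k}/k with circular
    indices.
    """
    if not 1 <= k <= K_SEQ:
        raise ValueError(f"k must be in 1..{K_SEQ}, got {k}")
    seq = np.asarray(seq, float)
    L = len(seq)
    fwd = seq[j] * seq[(j - k) % L] / k
    bwd = seq[j] * seq[(j + k) % L] / k
    return float(fwd), float(bwd)


def aaacf(seq: np.ndarray, j: int, k: int) -> float:
    """Circular window mean of the 2k+1 values centred at residue j."""
    if not 1 <= k <= K_SEQ:
        raise ValueError(f"k must be in 1..{K_SEQ}, got {k}")
    seq = np.asarray(seq, float)
    L = len(seq)
    window = [seq[(j + off) % L] for off in range(-k, k + 1)]
    return float(np.sum(window) / (2 * k + 1))


def neighbor_order(chain: ChainRecord, j: int) -> NeighborOrder:
    """Rank all other residues by ascending Cα distance from residue j.

    Equidistant residues order by ascending sequence position.  Structure
    features require 21 neighbours, so shorter chains are rejected.
    """
    L = len(chain)
    if L - 1 < K_STRUCT + 1:
        raise ValueError(
            f"chain {chain.chain_id}: structure features need at least "
            f"{K_STRUCT + 1} other residues, chain has {L - 1}"
        )
    diffs = chain.ca_coords - chain.ca_coords[j]
    d = np.sqrt((diffs**2).sum(axis=1))
    others = np.array([i for i in range(L) if i != j])
    order = others[np.lexsort((others, d[others]))]
    return NeighborOrder(center=j, lambda_=order, d=d[order])


def ripf(phi: np.ndarray, j: int, order: NeighborOrder, k: int) -> float:
    """φ_j · φ(λ_k) / k: product with the k-th nearest residue."""
    if not 1 <= k <= K_STRUCT:
        raise ValueError(f"k must be in 1..{K_STRUCT}, got {k}")
    phi = np.asarray(phi, float)
    return float(phi[j] * phi[order.lambda_[k - 1]] / k)


def racf(phi: np.ndarray, j: int, order: NeighborOrder, k: int) -> float:
    """Mean of the central value and its k nearest neighbours' values."""
    if not 1 <= k <= K_STRUCT:
        raise ValueError(f"k must be in 1..{K_STRUCT}, got {k}")
    phi = np.asarray(phi, float)
    return float((phi[j] + phi[order.lambda_[:k]].sum()) / (k + 1))


def neighbor_weights(
    order: NeighborOrder, k: int = K_STRUCT, literal: bool = False
) -> np.ndarray:
    """Distance weights ω_1..ω_{k+1} over the k+1 nearest residues.

    Default (scale-invariant) convention: ω_ξ = exp(−d_ξ²(k+1)/Σd²), where
    the sum runs over the k+1 nearest residues; all equal distances give
    ω ≡ e⁻¹.  The ``literal`` grouping exp(−d_ξ²)·(k+1)/Σd² is exposed for
    comparison but underflows at protein distance scales.
    """
    d = order.d[: k + 1]
    if len(d) < k + 1:
        raise ValueError(f"need {k + 1} neighbours, have {len(d)}")
    if np.any(d <= 0):
        raise ValueError("zero neighbour distance (duplicate coordinates)")
    denom = float((d**2).sum())
    if literal:
        return np.exp(-(d**2)) * (k + 1) / denom
    return np.exp(-(d**2) * (k + 1) / denom)


def rho(
    phi: np.ndarray, order: NeighborOrder, k: int = K_STRUCT, literal: bool = False
) -> np.ndarray:
    """ρ_ξ = ω_ξ · φ(λ_ξ) for ξ = 1..k (the k+1-th weight is not emitted)."""
    w = neighbor_weights(order, k, literal=literal)
    phi = np.asarray(phi, float)
    return w[:k] * phi[order.lambda_[:k]]


def residue_vector(
    chain: ChainRecord,
    physchem_seqs: np.ndarray,
    profile: GeometricProfile,
    j: int,
    order: NeighborOrder | None = None,
) -> np.ndarray:
    """The 460-feature vector of residue j (reference implementation).

    Ordering: per physicochemical property, (forward, backward) interval
    products for k = 1..10 then window means for k = 1..10; the five raw
    physicochemical values; per geometric property, interval products,
    cumulation factors and weighted values for k (ξ) = 1..20; the five raw
    geometric values.
    """
    if order is None:
        order = neighbor_order(chain, j)
    feats: list[float] = []
    for i in range(5):
        seq = physchem_seqs[i]
        for k in range(1, K_SEQ + 1):
            feats.extend(aaipf(seq, j, k))
        for k in range(1, K_SEQ + 1):
            feats.append(aaacf(seq, j, k))
    feats.extend(physchem_seqs[:, j])
    geo = profile.values.T
    for i in range(5):
        phi = geo[i]
        for k in range(1, K_STRUCT + 1):
            feats.append(ripf(phi, j, order, k))
        for k in range(1, K_STRUCT + 1):
            feats.append(racf(phi, j, order, k))
        feats.extend(rho(phi, order))
    feats.extend(geo[:, j])
    out = np.asarray(feats, float)
    assert out.shape == (N_RESIDUE_FEATURES,)
    return out


def chain_residue_vectors(
    chain: ChainRecord,
    profile: GeometricProfile,
    table: PhyschemTable,
) -> np.ndarray:
    """460-feature vectors for every residue of a chain, shape (L, 460).

    Vectorized across residues; equivalent to calling
    :func:`residue_vector` per residue.
    """
    L = len(chain)
    if L < K_STRUCT + 2:
        raise ValueError(
            f"chain {chain.chain_id}: structure features need at least "
            f"{K_STRUCT + 2} residues, chain has {L}"
        )
    phys = physchem_sequences(chain, table)  # (5, L)
    geo = profile.values.T  # (5, L)

    blocks: list[np.ndarray] = []
    # sequence block
    for i in range(5):
        seq = phys[i]
        cols = []
        for k in range(1, K_SEQ + 1):
            cols.append(seq * np.roll(seq, k) / k)  # forward
            cols.append(seq * np.roll(seq, -k) / k)  # backward
        acc = seq.copy()
        for k in range(1, K_SEQ + 1):
            acc = acc + np.roll(seq, k) + np.roll(seq, -k)
            cols.append(acc / (2 * k + 1))
        blocks.append(np.column_stack(cols))
    blocks.append(phys.T)

    # structure block
    dist = cdist(chain.ca_coords, chain.ca_coords)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")  # stable => index tiebreak
    nb = order[:, :K_STRUCT]  # (L, 20)
    d21 = np.take_along_axis(dist, order[:, : K_STRUCT + 1], axis=1)
    if np.any(d21 <= 0):
        raise ValueError("zero neighbour distance (duplicate coordinates)")
    denom = (d21**2).sum(axis=1, keepdims=True)
    omega = np.exp(-(d21[:, :K_STRUCT] ** 2) * (K_STRUCT + 1) / denom)
    ks = np.arange(1, K_STRUCT + 1)
    for i in range(5):
        phi = geo[i]
        phi_nb = phi[nb]  # (L, 20)
        ripf_m = phi[:, None] * phi_nb / ks
        racf_m = (phi[:, None] + np.cumsum(phi_nb, axis=1)) / (ks + 1)
        rho_m = omega * phi_nb
        blocks.append(np.concatenate([ripf_m, racf_m, rho_m], axis=1))
    blocks.append(geo.T)

    out = np.concatenate(blocks, axis=1)
    assert out.shape == (L, N_RESIDUE_FEATURES)
    return out


def pair_vector(
    u1: np.ndarray, u2: np.ndarray, label: int | None = None, **meta
) -> ResiduePairVector:
    """Order-sensitive concatenation of two residue vectors (chain 1 first)."""
    u1, u2 = np.asarray(u1, float), np.asarray(u2, float)
    if u1.shape != (N_RESIDUE_FEATURES,) or u2.shape != (N_RESIDUE_FEATURES,):
        raise ValueError("residue vectors must have 460 entries each")
    return ResiduePairVector(np.concatenate([u1, u2]), label=label, meta=meta)


def pair_matrix(
    U1: np.ndarray, U2: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Stack 920-d vectors for the given (i, j) residue-index pairs."""
    pairs = np.asarray(pairs, int)
    return np.concatenate([U1[pairs[:, 0]], U2[pairs[:, 1]]], axis=1)
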