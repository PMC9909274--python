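"""Self-contained synthetic tetramer complexes with planted signal.

Each complex is four Cα-trace chains laid out in space so that a chosen set
of chain pairs is in contact (labels are always *recomputed* from geometry
by :func:`tetraface.structures.label_contacts`, never asserted).  Two kinds
of signal are planted:

* **Chain level** — interacting chains are homologs: they share a clique
  ancestor (sequence drawn from a clique-specific composition, compact
  random-walk backbone) and diverge by point mutations and coordinate
  jitter, while chains of different cliques are unrelated.  Since the only
  pairwise statistic available to stage 1 is |Q_a − Q_b|, an interaction
  pattern must be (near-)transitive, so the interaction graph is a union of
  cliques: {ABCD}, a {2,2} split, or four singletons, sampled so the
  expected non-interacting fraction matches the configuration.
* **Residue level** — the five geometric properties emulate their
  structural meaning: ASA falls with intra-chain burial (neighbour count
  within 10 Å), ECA/ICA scale with inter-/intra-chain contact, EVA is a
  correlated mixture, all with Gaussian noise.  Interface residues thereby
  carry legitimate geometric signal without any label leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._aadata import ALPHABET, MAX_ASA, ONE_TO_THREE
from .structures import (
    CA_CUTOFF,
    ChainRecord,
    DatasetManifest,
    GeometricProfile,
    InterfaceLabels,
    ManifestEntry,
    PhyschemTable,
    TetramerComplex,
    label_contacts,
    write_property_table,
)

_CHAIN_IDS = ("A", "B", "C", "D")
_CLIQUE_SEPARATION = 200.0  # Å between clique centroids
_NEIGHBOR_RADIUS = 10.0  # Å, burial/contact neighbourhood


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic tetramer generator."""

    n_complexes: int = 12
    length_range: tuple[int, int] = (24, 60)
    noninteracting_fraction: float = 0.2
    interface_size_range: tuple[int, int] = (3, 40)
    property_noise: float = 2.0
    burial_coupling: float = 9.0
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (20 <= lo <= hi <= 500):
            raise ValueError("length_range must lie within [20, 500]")
        if not 0.0 <= self.noninteracting_fraction <= 1.0:
            raise ValueError("noninteracting_fraction must be in [0, 1]")
        if self.interface_size_range[0] < 1:
            raise ValueError("interface_size_range minimum must be >= 1")
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _compact_walk(L: int, rng: np.random.Generator) -> np.ndarray:
    """Compact, loosely self-avoiding Cα walk with 3.8 Å steps."""
    coords = [np.zeros(3)]
    for _ in range(L - 1):
        pos = coords[-1]
        best = None
        for _ in range(30):
            step = rng.normal(size=3) - 0.08 * pos
            step = 3.8 * step / np.linalg.norm(step)
            cand = pos + step
            if len(coords) < 3:
                best = cand
                break
            d = np.linalg.norm(np.array(coords[:-1]) - cand, axis=1)
            if d.min() >= 3.4:
                best = cand
                break
            if best is None or d.min() > np.linalg.norm(best - pos):
                best = cand
        coords.append(best)
    arr = np.array(coords)
    return arr - arr.mean(axis=0)


def _sample_cliques(
    fraction: float, rng: np.random.Generator
) -> list[list[int]]:
    """Partition of the four chains whose expected non-interacting
    chain-pair fraction equals ``fraction``."""
    if fraction <= 2.0 / 3.0:
        if rng.random() < 1.5 * fraction:
            perm = rng.permutation(4).tolist()
            return [sorted(perm[:2]), sorted(perm[2:])]
        return [[0, 1, 2, 3]]
    p_single = 3.0 * (fraction - 2.0 / 3.0)
    if rng.random() < p_single:
        return [[0], [1], [2], [3]]
    perm = rng.permutation(4).tolist()
    return [sorted(perm[:2]), sorted(perm[2:])]


def _contact_count(c1: np.ndarray, c2: np.ndarray) -> int:
    tree = cKDTree(c2)
    return int(sum(len(h) for h in tree.query_ball_point(c1, r=CA_CUTOFF)))


def _place_pair(
    c1: np.ndarray,
    c2: np.ndarray,
    size_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Translate c2 along a random axis until the Cα contact count with c1
    lands in ``size_range`` (best effort, at least the minimum)."""
    lo_n, hi_n = size_range
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    r1 = np.linalg.norm(c1, axis=1).max()
    r2 = np.linalg.norm(c2, axis=1).max()
    s_lo, s_hi = 2.0, r1 + r2 + CA_CUTOFF + 1.0
    best = None
    for _ in range(60):
        s = 0.5 * (s_lo + s_hi)
        n = _contact_count(c1, c2 + s * axis)
        if n < lo_n:
            s_hi = s
        elif n > hi_n:
            s_lo = s
        else:
            best = s
            break
        if lo_n <= n:
            best = s
    if best is None:
        # fall back to the largest separation that still meets the minimum
        s = s_lo
        while s > 1.0 and _contact_count(c1, c2 + s * axis) < lo_n:
            s *= 0.95
        best = s
    return c2 + best * axis


def _place_clique(
    coords: list[np.ndarray],
    size_range: tuple[int, int],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Arrange the clique members so every internal pair is in contact."""
    m = len(coords)
    if m == 1:
        return coords
    if m == 2:
        return [coords[0], _place_pair(coords[0], coords[1], size_range, rng)]
    # tetrahedral layout shrunk until the weakest pair meets the minimum
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
    ) / np.sqrt(3)
    radius = max(np.linalg.norm(c, axis=1).max() for c in coords)
    s = 2.0 * radius + CA_CUTOFF
    lo_n = size_range[0]
    for _ in range(300):
        placed = [c + s * v for c, v in zip(coords, verts)]
        weakest = min(
            _contact_count(placed[i], placed[j])
            for i in range(m)
            for j in range(i + 1, m)
        )
        if weakest >= lo_n:
            return placed
        s *= 0.97
    raise RuntimeError("could not realize an all-interacting tetramer layout")


def _profiles(
    chains: list[ChainRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, GeometricProfile]:
    all_coords = np.concatenate([c.ca_coords for c in chains])
    owner = np.repeat(np.arange(4), [len(c) for c in chains])
    tree = cKDTree(all_coords)
    neighbors = tree.query_ball_point(all_coords, r=_NEIGHBOR_RADIUS)
    out = {}
    offset = 0
    sigma = config.property_noise
    for ci, chain in enumerate(chains):
        L = len(chain)
        intra = np.zeros(L)
        inter = np.zeros(L)
        for local in range(L):
            g = offset + local
            for h in neighbors[g]:
                if h == g:
                    continue
                if owner[h] == ci:
                    intra[local] += 1
                else:
                    inter[local] += 1
        noise = lambda: rng.normal(0, sigma, L)  # noqa: E731
        asa = np.clip(100.0 - config.burial_coupling * intra + noise(), 0, None)
        max_asa = np.array([MAX_ASA[aa] for aa in chain.sequence])
        rasa = np.clip(asa / max_asa + rng.normal(0, 0.02, L), 0, None)
        eca = np.clip(4.0 * inter + noise(), 0, None)
        ica = np.clip(6.0 * intra + noise(), 0, None)
        eva = np.clip(0.5 * asa - 0.3 * eca + 20.0 + noise(), 0, None)
        out[chain.chain_id] = GeometricProfile(
            np.column_stack([asa, rasa, eca, ica, eva])
        )
        offset += L
    return out


def simulate_complex(
    config: SimulationConfig, index: int = 0
) -> tuple[TetramerComplex, dict[str, GeometricProfile], PhyschemTable, InterfaceLabels]:
    """Generate one tetramer complex with profiles and recomputed labels.

    Deterministic in ``(config.seed, index)``.  Geometry construction is
    retried a bounded number of times before giving up.
    """
    last_err: Exception | None = None
    for attempt in range(5):
        try:
            return _simulate_complex_once(config, index, attempt)
        except RuntimeError as exc:
            last_err = exc
    raise RuntimeError(
        f"complex {index}: infeasible geometry after bounded retries"
    ) from last_err


def _simulate_complex_once(
    config: SimulationConfig, index: int, attempt: int
) -> tuple[TetramerComplex, dict[str, GeometricProfile], PhyschemTable, InterfaceLabels]:
    rng = np.random.default_rng([config.seed, index, attempt])
    cliques = _sample_cliques(config.noninteracting_fraction, rng)

    seqs: list[str | None] = [None] * 4
    coords: list[np.ndarray | None] = [None] * 4
    for clique in cliques:
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        comp = rng.dirichlet(np.full(20, 2.0))
        ancestor_seq = rng.choice(list(ALPHABET), size=L, p=comp)
        ancestor_walk = _compact_walk(L, rng)
        member_coords = []
        for member in clique:
            seq = ancestor_seq.copy()
            mutate = rng.random(L) < config.mutation_rate
            seq[mutate] = rng.choice(list(ALPHABET), size=int(mutate.sum()), p=comp)
            seqs[member] = "".join(seq)
            jittered = ancestor_walk + rng.normal(0, 0.4, (L, 3))
            jittered = jittered @ _random_rotation(rng).T
            member_coords.append(jittered - jittered.mean(axis=0))
        placed = _place_clique(member_coords, config.interface_size_range, rng)
        for member, c in zip(clique, placed):
            coords[member] = c

    # separate the cliques so cross-clique pairs can never touch
    for q, clique in enumerate(cliques):
        shift = np.array([q * _CLIQUE_SEPARATION, 0.0, 0.0])
        for member in clique:
            coords[member] = coords[member] + shift

    chains = [
        ChainRecord(chain_id=_CHAIN_IDS[i], sequence=seqs[i], ca_coords=coords[i])
        for i in range(4)
    ]
    complex_ = TetramerComplex(complex_id=f"SYN{index:04d}", chains=chains)
    labels = label_contacts(complex_)

    # geometry must realize the planted clique structure
    clique_of = {m: q for q, cl in enumerate(cliques) for m in cl}
    for (cid1, cid2), interacting in labels.chain_pair_interactions.items():
        i1, i2 = _CHAIN_IDS.index(cid1), _CHAIN_IDS.index(cid2)
        expected = clique_of[i1] == clique_of[i2]
        if interacting != expected:
            raise RuntimeError(
                f"{complex_.complex_id}: layout failed to realize the "
                f"planted interaction graph for pair {cid1}{cid2}"
            )

    profiles = _profiles(chains, config, rng)
    return complex_, profiles, PhyschemTable.default(), labels


def _write_pdb(path: Path, complex_: TetramerComplex) -> None:
    structure = gemmi.Structure()
    structure.name = complex_.complex_id
    model = gemmi.Model("1")
    for chain in complex_.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for i, (aa, xyz) in enumerate(zip(chain.sequence, chain.ca_coords)):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[aa]
            res.seqid = gemmi.SeqId(chain.residue_ids[i], " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            res.add_atom(atom)
            gchain.add_residue(res)
        model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def _write_labels(path: Path, labels: InterfaceLabels) -> None:
    with open(path, "w") as fh:
        fh.write("chain1\tchain2\tres1\tres2\n")
        for (c1, c2), pairs in labels.interface_pairs.items():
            for i, j in sorted(pairs):
                fh.write(f"{c1}\t{c2}\t{i}\t{j}\n")


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> DatasetManifest:
    """Write ``n_complexes`` synthetic complexes and a 3:1 train/test manifest.

    Each complex yields a PDB file, one property TSV per chain and a label
    TSV; the physicochemical default table is written once.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_train = round(config.n_complexes * 0.75)
    entries = []
    for index in range(config.n_complexes):
        complex_, profiles, _, labels = simulate_complex(config, index)
        cid = complex_.complex_id
        pdb_path = out_dir / f"{cid}.pdb"
        _write_pdb(pdb_path, complex_)
        profile_paths = {}
        for chain in complex_.chains:
            p = out_dir / f"{cid}_{chain.chain_id}.tsv"
            write_property_table(p, chain, profiles[chain.chain_id])
            profile_paths[chain.chain_id] = p
        _write_labels(out_dir / f"{cid}.labels.tsv", labels)
        split = "train" if index < n_train else "test"
        entries.append(ManifestEntry(cid, split, pdb_path, profile_paths))
    manifest = DatasetManifest(entries)
    manifest.to_tsv(out_dir / "manifest.tsv")
    return manifest
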