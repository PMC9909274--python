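"""Complex structures, per-residue property tables, labels and manifests.

A tetramer complex is held as four :class:`ChainRecord` objects carrying the
one-letter sequence, the Cα trace and (when the source file had them) the
heavy-atom coordinates of every retained residue.  Residues without a Cα are
dropped at parse time.  Interface labels are defined geometrically: a residue
pair on two different chains is positive when the two residues are closer
than a cutoff, and a chain pair interacts iff it has at least one positive
residue pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._aadata import ALPHABET, GEOMETRIC_PROPERTIES, PHYSCHEM_PROPERTIES, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Cα–Cα contact cutoff (Å) used when only the Cα trace is available.
CA_CUTOFF = 8.0
#: minimum heavy-atom distance cutoff (Å) used on full-atom input.
HEAVY_CUTOFF = 5.0

PROPERTY_COLUMNS = ("residue_index", "aa") + GEOMETRIC_PROPERTIES


class ComplexError(ValueError):
    """Structure does not satisfy the tetramer-complex contract."""


class AlignmentError(ValueError):
    """A property table does not align with its chain."""


@dataclass
class ChainRecord:
    """One protein chain: sequence, Cα trace and optional heavy atoms."""

    chain_id: str
    sequence: str
    ca_coords: np.ndarray
    residue_ids: list[int] = field(default_factory=list)
    heavy_coords: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ComplexError(
                f"chain {self.chain_id}: ca_coords must be (L, 3), "
                f"got {self.ca_coords.shape}"
            )
        if len(self.sequence) != len(self.ca_coords):
            raise ComplexError(
                f"chain {self.chain_id}: sequence length {len(self.sequence)} "
                f"!= coordinate rows {len(self.ca_coords)}"
            )
        bad = sorted({c for c in self.sequence if c not in ALPHABET and c != "X"})
        if bad:
            raise ComplexError(
                f"chain {self.chain_id}: letters outside the amino-acid "
                f"alphabet: {bad}"
            )
        if not self.residue_ids:
            self.residue_ids = list(range(1, len(self.sequence) + 1))
        if len(self.residue_ids) != len(self.sequence):
            raise ComplexError(
                f"chain {self.chain_id}: residue_ids length mismatch"
            )
        if not 20 <= len(self.sequence) <= 500:
            warnings.warn(
                f"chain {self.chain_id} has {len(self.sequence)} residues, "
                "outside the 20-500 range expected for tetramer data",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TetramerComplex:
    """Exactly four chains with unique ids; yields six unordered chain pairs."""

    complex_id: str
    chains: list[ChainRecord]

    def __post_init__(self) -> None:
        if len(self.chains) != 4:
            raise ComplexError(
                f"{self.complex_id}: complex must have 4 chains, "
                f"got {len(self.chains)}"
            )
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != 4:
            raise ComplexError(f"{self.complex_id}: duplicate chain ids {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def chain_pairs(self) -> list[tuple[str, str]]:
        """The six unordered chain pairs in fixed (AB, AC, AD, BC, BD, CD) order."""
        return list(combinations(self.chain_ids, 2))


@dataclass
class GeometricProfile:
    """Per-residue ASA, RASA, ECA, ICA, EVA values for one chain."""

    values: np.ndarray  # (L, 5), column order GEOMETRIC_PROPERTIES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 5:
            raise AlignmentError(
                f"geometric profile must be (L, 5), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise AlignmentError("geometric profile contains non-finite values")
        if np.any(self.values[:, 0] < 0) or np.any(self.values[:, 1] < 0):
            raise AlignmentError("ASA and RASA must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, GEOMETRIC_PROPERTIES.index(name)]


@dataclass
class PhyschemTable:
    """20 amino acids x 5 physicochemical values."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [aa for aa in ALPHABET if aa not in self.values]
        if missing:
            raise ValueError(f"physicochemical table missing letters {missing}")
        for aa in ALPHABET:
            row = np.asarray(self.values[aa], dtype=float)
            if row.shape != (5,) or not np.all(np.isfinite(row)):
                raise ValueError(
                    f"physicochemical table row for {aa} must be 5 finite values"
                )
            self.values[aa] = row

    def row(self, aa: str) -> np.ndarray:
        if aa not in self.values:
            raise KeyError(f"no physicochemical values for letter {aa!r}")
        return self.values[aa]

    @classmethod
    def default(cls) -> "PhyschemTable":
        from ._aadata import default_physchem_rows

        return cls({aa: np.asarray(v) for aa, v in default_physchem_rows().items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhyschemTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = ("aa",) + PHYSCHEM_PROPERTIES
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(
            {
                str(r["aa"]): np.array([r[c] for c in PHYSCHEM_PROPERTIES], float)
                for _, r in df.iterrows()
            }
        )


@dataclass
class InterfaceLabels:
    """Per chain pair: positive residue-index pairs and the interaction flag.

    ``interface_pairs`` maps each unordered chain pair (in the fixed pair
    order) to the set of 0-based ``(i, j)`` index pairs labelled positive;
    the chain-pair interaction boolean is, by construction, non-emptiness of
    that set.
    """

    interface_pairs: dict[tuple[str, str], set[tuple[int, int]]]

    @property
    def chain_pair_interactions(self) -> dict[tuple[str, str], bool]:
        return {pair: len(s) > 0 for pair, s in self.interface_pairs.items()}

    def is_interacting(self, pair: tuple[str, str]) -> bool:
        return len(self.interface_pairs[pair]) > 0

    def n_interacting(self) -> int:
        return sum(self.chain_pair_interactions.values())


@dataclass
class ManifestEntry:
    complex_id: str
    split: str
    structure_path: Path
    profile_paths: dict[str, Path]


@dataclass
class DatasetManifest:
    """Flat list of complexes with split assignment and file locations."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        splits = {e.split for e in self.entries}
        bad = splits - {"train", "validation", "test"}
        if bad:
            raise ValueError(f"unknown split names {sorted(bad)}")
        ids = [e.complex_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate complex ids in manifest")

    def split(self, name: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == name]

    def validate_paths(self) -> None:
        for e in self.entries:
            if not e.structure_path.exists():
                raise FileNotFoundError(e.structure_path)
            for p in e.profile_paths.values():
                if not p.exists():
                    raise FileNotFoundError(p)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# complex_id\tsplit\tstructure\tprofiles"]
        for e in self.entries:
            profs = ";".join(f"{cid}={p}" for cid, p in e.profile_paths.items())
            lines.append(f"{e.complex_id}\t{e.split}\t{e.structure_path}\t{profs}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DatasetManifest":
        entries = []
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            cid, split, struct, profs = ln.split("\t")
            profile_paths = {}
            for item in profs.split(";"):
                chain_id, p = item.split("=", 1)
                profile_paths[chain_id] = Path(p)
            entries.append(ManifestEntry(cid, split, Path(struct), profile_paths))
        return cls(entries)


def read_complex(
    path: str | Path,
    chain_ids: list[str] | None = None,
    keep_heavy: bool = True,
) -> TetramerComplex:
    """Read a tetramer complex from a PDB file.

    Uses the first model and the first altloc of each atom.  Residues
    without a Cα atom are dropped with a logged warning.  Nonstandard
    residue names map to ``'X'`` (excluded from alphabet-indexed features).

    Parameters
    ----------
    chain_ids
        Explicit chains to keep.  Required when the file holds more than
        four chains; defaults to the first four otherwise.
    keep_heavy
        Retain per-residue heavy-atom coordinates for heavy-atom contact
        labeling when the file has more than the Cα trace.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise ComplexError(f"{path}: no models in file")
    model = structure[0]

    available = [ch.name for ch in model]
    if chain_ids is None:
        if len(available) > 4:
            raise ComplexError(
                f"{path}: {len(available)} chains present; pass an explicit "
                f"chain_ids list (available: {available})"
            )
        chain_ids = available[:4]

    chains: list[ChainRecord] = []
    for cid in chain_ids:
        ch = None
        for cand in model:
            if cand.name == cid:
                ch = cand
                break
        if ch is None:
            raise ComplexError(f"{path}: chain {cid!r} not found")
        seq, coords, res_ids, heavy = [], [], [], []
        for res in ch:
            if res.is_water():
                continue
            ca = next((a for a in res if a.name == "CA"), None)
            if ca is None:
                logger.warning(
                    "%s chain %s residue %s %s lacks a CA atom; dropped",
                    path.name, cid, res.seqid.num, res.name,
                )
                continue
            seq.append(THREE_TO_ONE.get(res.name, "X"))
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            res_ids.append(res.seqid.num)
            atoms = np.array(
                [
                    [a.pos.x, a.pos.y, a.pos.z]
                    for a in res
                    if not a.is_hydrogen() and a.altloc in ("", "\0", "A")
                ],
                dtype=float,
            )
            heavy.append(atoms if len(atoms) else np.array([[ca.pos.x, ca.pos.y, ca.pos.z]]))
        if not seq:
            continue
        has_heavy = keep_heavy and any(len(h) > 1 for h in heavy)
        chains.append(
            ChainRecord(
                chain_id=cid,
                sequence="".join(seq),
                ca_coords=np.array(coords),
                residue_ids=res_ids,
                heavy_coords=heavy if has_heavy else None,
            )
        )
    if len(chains) < 4:
        raise ComplexError(
            f"{path}: complex must have 4 chains with usable residues, "
            f"got {len(chains)}"
        )
    return TetramerComplex(complex_id=path.stem, chains=chains)


def read_property_table(path: str | Path, chain: ChainRecord) -> GeometricProfile:
    """Read a per-residue geometric property TSV aligned to ``chain``.

    The table must have columns residue_index, aa, ASA, RASA, ECA, ICA, EVA
    ('#' lines are comments), one row per retained residue, aligned to the
    chain by ``residue_index`` order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise AlignmentError(f"{path}: empty property table") from exc
    missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"{path}: missing columns {missing}")
    if len(df) != len(chain):
        raise AlignmentError(
            f"{path}: {len(df)} rows but chain {chain.chain_id} has "
            f"{len(chain)} residues"
        )
    df = df.sort_values("residue_index", kind="stable").reset_index(drop=True)
    mism = [
        (int(df.residue_index[i]), str(df.aa[i]), chain.sequence[i])
        for i in range(len(df))
        if str(df.aa[i]) != chain.sequence[i]
    ]
    if mism:
        raise AlignmentError(
            f"{path}: residue letters disagree with chain {chain.chain_id} at "
            f"rows {mism[:10]}"
        )
    vals = df[list(GEOMETRIC_PROPERTIES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad_rows = np.where(~np.isfinite(vals).all(axis=1))[0].tolist()
        raise AlignmentError(f"{path}: non-numeric values at rows {bad_rows[:10]}")
    return GeometricProfile(vals)


def write_property_table(
    path: str | Path, chain: ChainRecord, profile: GeometricProfile
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PROPERTY_COLUMNS) + "\n")
        for i in range(len(chain)):
            row = "\t".join(f"{v:.4f}" for v in profile.values[i])
            fh.write(f"{chain.residue_ids[i]}\t{chain.sequence[i]}\t{row}\n")


def load_entry(
    entry: ManifestEntry, cutoff: float | None = None
) -> tuple[TetramerComplex, dict[str, GeometricProfile], InterfaceLabels]:
    """Read one manifest entry and recompute its contact labels."""
    complex_ = read_complex(entry.structure_path, list(entry.profile_paths))
    profiles = {
        cid: read_property_table(path, complex_.chain(cid))
        for cid, path in entry.profile_paths.items()
    }
    return complex_, profiles, label_contacts(complex_, cutoff)


def label_contacts(
    complex_: TetramerComplex, cutoff: float | None = None
) -> InterfaceLabels:
    """Label interface residue pairs by spatial proximity.

    A residue pair (i on chain 1, j on chain 2) is positive when the two
    residues are within ``cutoff`` Å — minimum heavy-atom distance when all
    four chains carry heavy atoms (default 5.0 Å), Cα–Cα otherwise
    (default 8.0 Å).  A chain pair interacts iff it has a positive pair.
    """
    heavy_mode = all(c.heavy_coords is not None for c in complex_.chains)
    if cutoff is None:
        cutoff = HEAVY_CUTOFF if heavy_mode else CA_CUTOFF
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for c in complex_.chains:
        if not np.all(np.isfinite(c.ca_coords)):
            raise ComplexError(f"chain {c.chain_id}: non-finite coordinates")

    interface: dict[tuple[str, str], set[tuple[int, int]]] = {}
    for cid1, cid2 in complex_.chain_pairs():
        c1, c2 = complex_.chain(cid1), complex_.chain(cid2)
        if heavy_mode:
            pairs = _heavy_contacts(c1, c2, cutoff)
        else:
            pairs = _ca_contacts(c1, c2, cutoff)
        interface[(cid1, cid2)] = pairs
    return InterfaceLabels(interface)


def _ca_contacts(
    c1: ChainRecord, c2: ChainRecord, cutoff: float
) -> set[tuple[int, int]]:
    tree = cKDTree(c2.ca_coords)
    hits = tree.query_ball_point(c1.ca_coords, r=cutoff)
    return {(i, j) for i, js in enumerate(hits) for j in js}

def _heavy_contacts(
    c1: ChainRecord, c2: ChainRecord, cutoff: float
) -> set[tuple[int, int]]:
    a1 = np.concatenate(c1.heavy_coords)
    a2 = np.concatenate(c2.heavy_coords)
    owner1 = np.repeat(np.arange(len(c1)), [len(h) for h in c1.heavy_coords])
    owner2 = np.repeat(np.arange(len(c2)), [len(h) for h in c2.heavy_coords])
    tree = cKDTree(a2)
    hits = tree.query_ball_point(a1, r=cutoff)
    return {
        (int(owner1[i]), int(owner2[j])) for i, js in enumerate(hits) for j in js
    }
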