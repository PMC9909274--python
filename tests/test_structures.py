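"""Structure/profile I/O, contact labeling and manifest handling."""

from __future__ import annotations

import numpy as np
import pytest

from tetraface import (
    DatasetManifest,
    GeometricProfile,
    PhyschemTable,
    TetramerComplex,
    label_contacts,
    read_complex,
    read_property_table,
    simulate_complex,
    simulate_dataset,
    write_property_table,
)
from tetraface.simulate import SimulationConfig, _write_pdb
from tetraface.structures import AlignmentError, ComplexError

from conftest import WORKED_ASA, WORKED_SEQUENCE, make_chain


@pytest.fixture
def small_complex(tmp_path):
    config = SimulationConfig(n_complexes=1, length_range=(30, 30), seed=42)
    complex_, profiles, _, labels = simulate_complex(config, 0)
    pdb = tmp_path / "syn.pdb"
    _write_pdb(pdb, complex_)
    return complex_, profiles, labels, pdb


class TestReadComplex:
    def test_round_trip_preserves_sequences_and_lengths(self, small_complex):
        complex_, _, _, pdb = small_complex
        loaded = read_complex(pdb)
        assert loaded.chain_ids == complex_.chain_ids
        for orig, new in zip(complex_.chains, loaded.chains):
            assert new.sequence == orig.sequence
            assert len(new) == 30
            np.testing.assert_allclose(new.ca_coords, orig.ca_coords, atol=1e-2)

    def test_residue_without_ca_is_dropped_with_warning(self, small_complex, caplog):
        _, _, _, pdb = small_complex
        lines = pdb.read_text().splitlines()
        ca_lines = [i for i, l in enumerate(lines)
                    if l.startswith("ATOM") and " CA " in l and l[21:22] == "A"]
        # turn one residue's only CA into a CB: residue retained in the
        # file but unusable for the trace
        lines[ca_lines[5]] = lines[ca_lines[5]].replace(" CA ", " CB ", 1)
        trimmed = pdb.parent / "trimmed.pdb"
        trimmed.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            loaded = read_complex(trimmed)
        assert len(loaded.chain("A")) == 29
        assert any("lacks a CA atom" in r.getMessage() for r in caplog.records)

    def test_three_chain_file_is_rejected(self, small_complex, tmp_path):
        _, _, _, pdb = small_complex
        lines = [l for l in pdb.read_text().splitlines()
                 if not (l.startswith(("ATOM", "TER")) and l[21:22] == "D")]
        bad = tmp_path / "three.pdb"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ComplexError, match="4 chains"):
            read_complex(bad)

    def test_unparseable_file_raises_io_error(self, tmp_path):
        bad = tmp_path / "junk.pdb"
        bad.write_bytes(b"\x00\x01 not a pdb")
        with pytest.raises((IOError, ComplexError)):
            read_complex(bad)


class TestPropertyTable:
    def test_worked_example_asa_column_round_trips(self, tmp_path, worked_chain):
        chain, profile = worked_chain
        path = tmp_path / "props.tsv"
        write_property_table(path, chain, profile)
        loaded = read_property_table(path, chain)
        np.testing.assert_allclose(loaded.column("ASA"), WORKED_ASA)

    def test_empty_file_is_rejected(self, tmp_path, worked_chain):
        chain, _ = worked_chain
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(AlignmentError):
            read_property_table(path, chain)

    def test_row_count_mismatch_is_rejected(self, tmp_path, worked_chain):
        chain, profile = worked_chain
        path = tmp_path / "short.tsv"
        write_property_table(path, chain, profile)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(AlignmentError, match="rows"):
            read_property_table(path, chain)

    def test_letter_mismatch_names_offending_rows(self, tmp_path, worked_chain):
        chain, profile = worked_chain
        path = tmp_path / "mismatch.tsv"
        write_property_table(path, chain, profile)
        text = path.read_text().replace(f"2\tC\t", "2\tW\t")
        path.write_text(text)
        with pytest.raises(AlignmentError, match="disagree"):
            read_property_table(path, chain)

    def test_missing_column_is_rejected(self, tmp_path, worked_chain):
        chain, _ = worked_chain
        path = tmp_path / "cols.tsv"
        path.write_text("residue_index\taa\tASA\n" +
                        "\n".join(f"{i+1}\t{aa}\t1.0" for i, aa in
                                  enumerate(WORKED_SEQUENCE)))
        with pytest.raises(AlignmentError, match="missing columns"):
            read_property_table(path, chain)


class TestLabelContacts:
    @staticmethod
    def _complex_from_coords(coords: dict[str, np.ndarray]) -> TetramerComplex:
        chains = [make_chain("A" * len(c), c, cid) for cid, c in coords.items()]
        return TetramerComplex("test", chains)

    def test_distant_chains_do_not_interact(self, rng):
        base = rng.normal(size=(25, 3))
        coords = {cid: base + off for cid, off in
                  zip("ABCD", [[0, 0, 0], [100, 0, 0], [0, 100, 0], [100, 100, 0]])}
        labels = label_contacts(self._complex_from_coords(coords))
        assert labels.n_interacting() == 0
        assert all(len(s) == 0 for s in labels.interface_pairs.values())

    def test_single_close_pair_is_the_only_positive(self, rng):
        a = np.column_stack([np.arange(25) * 12.0, np.zeros(25), np.zeros(25)])
        b = a + np.array([0.0, 50.0, 0.0])
        b[7] = a[3] + np.array([0.0, 3.0, 0.0])  # one residue pair at 3 Å
        coords = {"A": a, "B": b,
                  "C": a + np.array([0, 500, 0.0]), "D": a + np.array([0, 900, 0.0])}
        labels = label_contacts(self._complex_from_coords(coords), cutoff=8.0)
        assert labels.interface_pairs[("A", "B")] == {(3, 7)}
        assert labels.is_interacting(("A", "B"))
        assert labels.n_interacting() == 1

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        config = SimulationConfig(n_complexes=1, length_range=(40, 40), seed=9)
        complex_, _, _, labels = simulate_complex(config, 0)
        for cid1, cid2 in complex_.chain_pairs():
            c1, c2 = complex_.chain(cid1), complex_.chain(cid2)
            oracle = {
                (i, j)
                for i in range(len(c1))
                for j in range(len(c2))
                if np.linalg.norm(c1.ca_coords[i] - c2.ca_coords[j]) <= 8.0
            }
            assert labels.interface_pairs[(cid1, cid2)] == oracle

    def test_interaction_flag_iff_nonempty_interface(self):
        config = SimulationConfig(n_complexes=4, seed=3, noninteracting_fraction=0.5)
        for i in range(4):
            _, _, _, labels = simulate_complex(config, i)
            for pair, pairs in labels.interface_pairs.items():
                assert labels.chain_pair_interactions[pair] == (len(pairs) > 0)

    def test_candidate_pair_count_is_l1_times_l2(self):
        config = SimulationConfig(n_complexes=1, seed=5)
        complex_, _, _, _ = simulate_complex(config, 0)
        assert len(complex_.chain_pairs()) == 6
        for cid1, cid2 in complex_.chain_pairs():
            n = len(complex_.chain(cid1)) * len(complex_.chain(cid2))
            assert n > 0  # full candidate grid is L1 x L2 by construction


class TestManifest:
    def test_round_trip_and_split_sizes(self, tmp_path):
        config = SimulationConfig(n_complexes=4, seed=0)
        manifest = simulate_dataset(config, tmp_path)
        loaded = DatasetManifest.from_tsv(tmp_path / "manifest.tsv")
        assert [e.complex_id for e in loaded.entries] == [
            e.complex_id for e in manifest.entries
        ]
        loaded.validate_paths()
        train_ids = {e.complex_id for e in loaded.split("train")}
        test_ids = {e.complex_id for e in loaded.split("test")}
        assert train_ids.isdisjoint(test_ids)
        assert len(train_ids) + len(test_ids) == 4


class TestPhyschemTable:
    def test_default_table_is_complete(self):
        table = PhyschemTable.default()
        assert all(table.row(aa).shape == (5,) for aa in "ACDEFGHIKLMNPQRSTVWY")

    def test_tsv_round_trip(self, tmp_path):
        table = PhyschemTable.default()
        path = tmp_path / "physchem.tsv"
        from tetraface._aadata import ALPHABET, PHYSCHEM_PROPERTIES
        header = "aa\t" + "\t".join(PHYSCHEM_PROPERTIES)
        rows = [header] + [
            aa + "\t" + "\t".join(str(v) for v in table.row(aa)) for aa in ALPHABET
        ]
        path.write_text("\n".join(rows) + "\n")
        loaded = PhyschemTable.from_tsv(path)
        for aa in ALPHABET:
            np.testing.assert_allclose(loaded.row(aa), table.row(aa))

    def test_missing_letter_is_rejected(self):
        rows = PhyschemTable.default().values
        rows.pop("W")
        with pytest.raises(ValueError, match="missing letters"):
            PhyschemTable(rows)


def test_profile_rejects_negative_asa():
    vals = np.ones((25, 5))
    vals[3, 0] = -1.0
    with pytest.raises(AlignmentError, match="non-negative"):
        GeometricProfile(vals)
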